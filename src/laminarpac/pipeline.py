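"""End-to-end pipeline on synthetic sham/injured cohorts.

Runs the full analysis chain — synthesis, channel alignment, power maps,
CSD, phase-amplitude coupling, unit classification, entrainment, and
septal coupling — and collects the group-level statistics into a single
machine-readable summary.  Every stage is a pure function of the
configuration and seed, so reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import ttest_ind

from . import classify as cls
from . import synth
from .core import AlignedCohort
from .csd import csd_standard
from .entrain import SR_BAND, entrain_unit, entrainment_channel
from .pac import comodulogram, compare_comodulograms
from .septal import detect_troughs, psth, spike_triggered_average
from .spectral import align_to_pyramidale, pdd_map, welch_psd

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("synth", "align", "pdd", "csd", "pac", "classify",
              "entrain", "septal")

# offset separating the sham and injured random streams
_GROUP_SEED_OFFSET = 10_000_019


@dataclass
class PipelineConfig:
    seed: int = 0
    n_animals: int = 3
    duration_s: float = 60.0
    fs: float = 1000.0
    n_channels: int = 32
    n_pyr: int = 8
    n_int: int = 6
    n_ms_gaba: int = 10
    n_ms_chol: int = 4
    low_band: tuple[float, float] = SR_BAND
    theta_band: tuple[float, float] = (2.0, 5.0)
    pac_phase_freqs: tuple[float, float, float] = (1.0, 20.0, 1.0)   # lo, hi, step
    pac_amp_freqs: tuple[float, float, float] = (10.0, 300.0, 5.0)
    alpha: float = 0.05
    stages: tuple[str, ...] = ALL_STAGES
    out_dir: str | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown pipeline stage(s): {sorted(unknown)}")
        if self.fs < 2.0 * self.pac_amp_freqs[1]:
            raise ValueError("fs too low for the requested PAC amplitude range")

    @classmethod
    def from_file(cls_, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls_(**{k: tuple(v) if isinstance(v, list) else v
                      for k, v in raw.items()})
        return cfg

    def to_file(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self)))


def _spec(cfg: PipelineConfig, seed: int) -> synth.CohortSpec:
    return synth.CohortSpec(
        n_animals=cfg.n_animals, duration_s=cfg.duration_s, fs=cfg.fs,
        n_channels=cfg.n_channels, n_pyr=cfg.n_pyr, n_int=cfg.n_int,
        n_ms_gaba=cfg.n_ms_gaba, n_ms_chol=cfg.n_ms_chol, seed=seed,
    )


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _band_sel(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (freqs >= lo) & (freqs <= hi)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and return the summary dictionary."""
    cfg.validate()
    summary: dict = {"seed": cfg.seed, "stages": list(cfg.stages)}
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    cohorts: dict[str, synth.Cohort] = {}
    aligned: dict[str, AlignedCohort] = {}

    def stage_enabled(name: str) -> bool:
        return name in cfg.stages

    # --- synth -----------------------------------------------------------
    cohorts["sham"] = synth.make_cohort(_spec(cfg, cfg.seed), synth.sham_effects())
    cohorts["injured"] = synth.make_cohort(
        _spec(cfg, cfg.seed + _GROUP_SEED_OFFSET), synth.injured_effects())
    if stage_enabled("synth"):
        summary["synth"] = {
            g: {"n_animals": c.spec.n_animals,
                "n_ca1_units": len(c.ca1_units),
                "n_ms_units": len(c.ms_units)}
            for g, c in cohorts.items()
        }

    # --- align -----------------------------------------------------------
    for g, c in cohorts.items():
        aligned[g] = align_to_pyramidale(c.recordings)
    if stage_enabled("align"):
        summary["align"] = {
            g: {"sp_indices": {a: int(i) for a, i in al.sp_indices.items()},
                "n_window": al.n_window}
            for g, al in aligned.items()
        }

    # --- pdd -------------------------------------------------------------
    if stage_enabled("pdd"):
        stacks = {}
        for g, al in aligned.items():
            stacks[g] = []
            for rec in al.recordings:
                ps = welch_psd(rec, fmax=min(300.0, 0.45 * cfg.fs))
                ps.power = ps.power[al.window_map[rec.animal_id]]
                stacks[g].append(ps)
        pm = pdd_map(stacks["sham"], stacks["injured"], alpha=cfg.alpha)
        sp_row = aligned["sham"].sp_aligned_index
        sr_rows = slice(sp_row + 6, pm.pdd.shape[0])
        low_sel = _band_sel(pm.freqs, 10.0, 15.0)
        high_sel = _band_sel(pm.freqs, 120.0, pm.freqs[-1])
        low_block = pm.masked_pdd[sr_rows, :][:, low_sel]
        high_block = pm.masked_pdd[sp_row - 1: sp_row + 2, :][:, high_sel]
        i_low = np.unravel_index(np.argmin(low_block), low_block.shape)
        i_high = np.unravel_index(np.argmin(high_block), high_block.shape)
        summary["pdd"] = {
            "sr_low_peak_reduction_pct": float(-low_block[i_low]),
            "sr_low_peak_freq_hz": float(pm.freqs[low_sel][i_low[1]]),
            "sp_high_peak_reduction_pct": float(-high_block[i_high]),
            "sp_high_peak_freq_hz": float(pm.freqs[high_sel][i_high[1]]),
            "frac_significant": float(pm.mask.mean()),
        }
        if out_dir:
            np.savetxt(out_dir / "pdd_masked.csv", pm.masked_pdd, delimiter=",")

    # --- csd -------------------------------------------------------------
    if stage_enabled("csd"):
        al = aligned["sham"]
        rec = al.recordings[0]
        truth = cohorts["sham"].truths[rec.animal_id]
        t_mid = float(truth["trough_times"][len(truth["trough_times"]) // 2])
        cm = csd_standard(rec, band=(2.0, 20.0),
                          t0=max(0.0, t_mid - 0.25), t1=t_mid + 0.25)
        # sink location at the trough of the SR wave, in original channel index
        col = cm.csd.shape[1] // 2
        sink_ch = int(np.argmin(cm.csd[:, col])) + cm.channel_offset
        summary["csd"] = {
            "sink_channel": sink_ch,
            "sp_channel": int(al.sp_indices[rec.animal_id]),
            "sink_below_sp": bool(sink_ch > al.sp_indices[rec.animal_id]),
        }

    # --- pac -------------------------------------------------------------
    if stage_enabled("pac"):
        lo, hi, st = cfg.pac_phase_freqs
        phase_freqs = np.arange(lo, hi + st / 2, st)
        lo, hi, st = cfg.pac_amp_freqs
        amp_freqs = np.arange(lo, hi + st / 2, st)
        comods = {}
        for g, al in aligned.items():
            comods[g] = []
            for rec in al.recordings:
                sp_sig = rec.lfp[al.window_map[rec.animal_id][al.sp_aligned_index]]
                sr_idx = entrainment_channel(al.sp_aligned_index, rec.spacing_um)
                sr_sig = rec.lfp[al.window_map[rec.animal_id][sr_idx]]
                comods[g].append(comodulogram(
                    sr_sig, sp_sig, rec.fs, phase_freqs=phase_freqs,
                    amp_freqs=amp_freqs))
        mean_sham = np.mean([c.mi for c in comods["sham"]], axis=0)
        i, j = np.unravel_index(np.argmax(mean_sham), mean_sham.shape)
        pac_summary = {
            "sham_peak_phase_freq_hz": float(phase_freqs[i]),
            "sham_peak_amp_freq_hz": float(amp_freqs[j]),
            "sham_peak_mi": float(mean_sham[i, j]),
            "injured_mi_at_sham_peak": float(
                np.mean([c.mi[i, j] for c in comods["injured"]])),
        }
        if len(comods["sham"]) >= 2 and len(comods["injured"]) >= 2:
            diff, pvals = compare_comodulograms(comods["sham"], comods["injured"])
            band = _band_sel(amp_freqs, 190.0, 280.0)
            sig_loss = (pvals[:, band] < cfg.alpha) & (diff[:, band] > 0)
            pac_summary["n_sig_loss_cells_190_280"] = int(sig_loss.sum())
        summary["pac"] = pac_summary

    # --- classify --------------------------------------------------------
    if stage_enabled("classify"):
        res = {}
        for g, c in cohorts.items():
            ca1_counts = {"pyramidal": 0, "interneuron": 0, "unclassified": 0}
            rates: dict[str, list[float]] = {"pyramidal": [], "interneuron": []}
            for rec in c.recordings:
                units = c.units_for(rec.animal_id, "CA1")
                labels = cls.classify_ca1(
                    units, aligned[g].sp_indices[rec.animal_id],
                    duration_s=cfg.duration_s, n_channels=cfg.n_channels)
                for u, lab in zip(units, labels):
                    ca1_counts[lab.subtype] += 1
                    if lab.subtype in rates:
                        rates[lab.subtype].append(u.firing_rate(cfg.duration_s))
            ms_labels = cls.classify_ms(c.ms_units, duration_s=cfg.duration_s)
            ms_counts = {"GABA/Glu": 0, "cholinergic": 0, "unclassified": 0}
            ms_rates: dict[str, list[float]] = {"GABA/Glu": [], "cholinergic": []}
            for lab in ms_labels:
                ms_counts[lab.subtype] += 1
                if lab.subtype in ms_rates:
                    ms_rates[lab.subtype].append(lab.rate_hz)
            res[g] = {
                "ca1_counts": ca1_counts,
                "ca1_mean_rate_hz": {k: float(np.mean(v)) if v else None
                                     for k, v in rates.items()},
                "ms_counts": ms_counts,
                "ms_mean_rate_hz": {k: float(np.mean(v)) if v else None
                                    for k, v in ms_rates.items()},
                "_ca1_rates": rates,
                "_ms_rates": ms_rates,
            }
        for region, key in (("ca1_pyramidal", "_ca1_rates"),):
            a = res["sham"][key]["pyramidal"]
            b = res["injured"][key]["pyramidal"]
            if len(a) >= 2 and len(b) >= 2:
                _, p = ttest_ind(a, b, equal_var=False)
                res[f"{region}_rate_welch_p"] = float(p)
        a, b = res["sham"]["_ms_rates"]["GABA/Glu"], res["injured"]["_ms_rates"]["GABA/Glu"]
        if len(a) >= 2 and len(b) >= 2:
            _, p = ttest_ind(a, b, equal_var=False)
            res["ms_gaba_rate_welch_p"] = float(p)
        for g in cohorts:
            res[g].pop("_ca1_rates")
            res[g].pop("_ms_rates")
        summary["classify"] = res

    # --- entrain ---------------------------------------------------------
    entrain_results: dict[str, dict[str, list]] = {}
    if stage_enabled("entrain") or stage_enabled("septal"):
        for g, c in cohorts.items():
            entrain_results[g] = {"pyramidal": [], "interneuron": [], "ms": []}
            for rec in c.recordings:
                al = aligned[g]
                sr_idx = entrainment_channel(al.sp_aligned_index, rec.spacing_um)
                chan = rec.lfp[al.window_map[rec.animal_id][sr_idx]]
                for u in c.units_for(rec.animal_id, "CA1"):
                    if u.n_spikes < 10:
                        continue
                    er = entrain_unit(u, chan, rec.fs, band=cfg.low_band,
                                      alpha=cfg.alpha)
                    entrain_results[g][u.truth["subtype"]].append(er)
                for u in c.units_for(rec.animal_id, "MS"):
                    if u.n_spikes < 10:
                        continue
                    er = entrain_unit(u, chan, rec.fs, band=cfg.low_band,
                                      alpha=cfg.alpha)
                    entrain_results[g]["ms"].append(er)
    if stage_enabled("entrain"):
        ent = {}
        for g, pools in entrain_results.items():
            ent[g] = {}
            for pool, results in pools.items():
                if not results:
                    continue
                entrained = [r for r in results if r.entrained]
                ent[g][pool] = {
                    "n": len(results),
                    "n_entrained": len(entrained),
                    "pct_entrained": 100.0 * len(entrained) / len(results),
                    "mean_resultant": float(np.mean(
                        [r.resultant_length for r in entrained])) if entrained else None,
                    "mean_phase_deg": float(np.degrees(np.angle(np.mean(
                        [np.exp(1j * np.radians(r.mean_angle_deg))
                         for r in entrained])))) % 360.0 if entrained else None,
                }
        summary["entrain"] = ent

    # --- septal ----------------------------------------------------------
    if stage_enabled("septal"):
        sep = {}
        for g, c in cohorts.items():
            modulated_ids = {r.unit_id for r in entrain_results[g]["ms"]
                             if r.entrained}
            p2ps, dips, baselines = [], [], []
            for rec in c.recordings:
                al = aligned[g]
                sr_idx = entrainment_channel(al.sp_aligned_index, rec.spacing_um)
                chan_idx = al.window_map[rec.animal_id][sr_idx]
                chan = rec.lfp[chan_idx]
                deep_sr = al.window_map[rec.animal_id][-1]
                troughs = detect_troughs(chan, rec.fs, cfg.low_band)
                for u in c.units_for(rec.animal_id, "MS"):
                    if u.unit_id not in modulated_ids:
                        continue
                    sta = spike_triggered_average(u, rec, p2p_channel=deep_sr)
                    p2ps.append(sta.p2p_uv)
                    ph = psth(u, troughs)
                    centers = ph.bin_centers_ms
                    dip_sel = (centers >= 12.0) & (centers <= 20.0)
                    base_sel = centers < 0.0
                    dips.append(ph.prob[dip_sel].mean())
                    baselines.append(ph.prob[base_sel].mean())
            sep[g] = {
                "n_modulated_ms_units": len(p2ps),
                "mean_sta_p2p_uv": float(np.mean(p2ps)) if p2ps else None,
                "psth_dip_ratio": (float(np.mean(dips) / np.mean(baselines))
                                   if dips and np.mean(baselines) > 0 else None),
            }
        summary["septal"] = sep

    if out_dir:
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True, default=_json_default))
    return summary
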