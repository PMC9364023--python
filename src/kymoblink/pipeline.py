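"""End-to-end replication runs: simulate -> analyze -> fit -> report.

`run_replication` wires every stage together under one seed and writes all
intermediate artifacts plus a single JSON summary into a run directory. The
default configuration mirrors the study design: two conditions of 50
simulated 60 s kymographs fitted jointly with the linked dual-Poisson
mixture, a two-color stoichiometry experiment per condition, and
FRET/CD spectra with positive and null couplings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import blink, kymo, simulate, spectra, stoich

__all__ = ["RunConfig", "run_replication"]


@dataclass
class RunConfig:
    """Declarative configuration of one replication run (JSON-serializable)."""

    seed: int = 0
    outdir: str = "kymoblink_run"
    # blink-mixture experiment: condition label -> monomer amplitude alpha
    bl_mon: float = 10.8
    duration_s: float = 60.0
    blink_alphas: dict = field(
        default_factory=lambda: {"condition_a": 0.129, "condition_b": 0.542}
    )
    n_kymographs: int = 50
    n_bootstrap: int = 1000
    image_level: bool = False  # simulate/analyze actual kymograph images
    # dual-color experiment: condition label -> true dimer fraction
    dual_color_fractions: dict = field(
        default_factory=lambda: {"condition_a": 0.94, "condition_b": 0.30}
    )
    n_molecules: int = 1000
    color_probs: tuple = (0.5, 0.5)
    label_efficiency: float = 1.0
    # spectra experiment
    fret_coupling: float = 0.5
    cd_coupling: float = 0.5
    verbosity: int = 1

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _log(cfg: RunConfig, msg: str) -> None:
    if cfg.verbosity > 0:
        print(f"[kymoblink] {msg}")


def _blink_counts_for_condition(cfg: RunConfig, alpha: float, seed: int) -> np.ndarray:
    if not cfg.image_level:
        params = simulate.MixtureSimParams(
            bl_mon=cfg.bl_mon,
            duration_s=cfg.duration_s,
            alpha=alpha,
            n_kymographs=cfg.n_kymographs,
            seed=seed,
        )
        return simulate.simulate_blink_counts(params)
    # full image path: choose monomer/dimer per kymograph, render, fit, count
    rng = np.random.default_rng(seed)
    counts = []
    rate = cfg.bl_mon / cfg.duration_s
    for i in range(cfg.n_kymographs):
        is_mon = rng.random() < alpha
        params = simulate.KymoSimParams(
            duration_s=cfg.duration_s,
            blink_rate_per_s=rate,
            n_emitters=1 if is_mon else 2,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        km, _ = simulate.simulate_kymograph(params)
        track = kymo.fit_kymograph(km)
        on = kymo.classify_frames(track)
        series = kymo.count_blinks(on, frame_interval_s=km.frame_interval_s, id=km.id)
        counts.append(series.n_blinks)
    return np.array(counts, dtype=int)


def run_replication(config: RunConfig) -> dict:
    """Run the full pipeline under one seed; returns the summary dict.

    Writes per-stage CSV/JSON artifacts, a run manifest, and
    ``summary.json`` into ``config.outdir``. Identical (config, seed) pairs
    give byte-identical summaries.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {"config": asdict(config), "seed": config.seed}

    def _write(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest.append(name)

    # --- stage 1: blink mixture ------------------------------------------
    _log(config, "stage 1/3: blink-count simulation and dual-Poisson fit")
    labels = list(config.blink_alphas)
    if len(labels) != 2:
        raise ValueError("blink stage requires exactly two conditions")
    counts = {}
    hists = {}
    for i, lab in enumerate(labels):
        c = _blink_counts_for_condition(
            config, float(config.blink_alphas[lab]), config.seed + 1000 + i
        )
        counts[lab] = c
        hists[lab] = blink.histogram_from_counts(c, config.duration_s)
        _write(
            f"blink_counts_{lab}.csv",
            lambda p, c=c: pd.DataFrame(
                {"kymograph_id": np.arange(c.size), "blink_count": c}
            ).to_csv(p, index=False),
        )
    fit = blink.fit_dual_poisson(
        hists[labels[0]],
        hists[labels[1]],
        n_bootstrap=config.n_bootstrap,
        seed=config.seed + 2000,
        counts_a=counts[labels[0]],
        counts_b=counts[labels[1]],
    )
    _write("blink_fit.json", lambda p: blink.write_fit_report(fit, p))
    _write(
        "blink_fit_curves.csv",
        lambda p: blink.fitted_vs_observed(
            fit, [hists[labels[0]], hists[labels[1]]], labels
        ).to_csv(p, index=False),
    )
    summary["blink_fit"] = fit.to_dict()
    summary["blink_fit"]["condition_labels"] = labels

    # --- stage 2: dual-color stoichiometry -------------------------------
    _log(config, "stage 2/3: dual-color labeling and dimer-fraction estimate")
    summary["dual_color"] = {}
    for i, (lab, frac) in enumerate(config.dual_color_fractions.items()):
        obs = simulate.simulate_dual_color_population(
            n_molecules=config.n_molecules,
            dimer_fraction=float(frac),
            color_probs=tuple(config.color_probs),
            seed=config.seed + 3000 + i,
            label_efficiency=config.label_efficiency,
        )
        est = stoich.estimate_dimer_fraction(
            obs, tuple(config.color_probs), config.label_efficiency
        )
        _write(
            f"dual_color_counts_{lab}.csv",
            lambda p, obs=obs: obs.to_frame().to_csv(p, index=False),
        )
        d = est.to_dict()
        d["true_dimer_fraction"] = float(frac)
        summary["dual_color"][lab] = d

    # --- stage 3: spectra -------------------------------------------------
    _log(config, "stage 3/3: FRET and CD difference spectra")
    summary["spectra"] = {}
    spec_runs = [
        ("fret_coupled", "fret_excitation", config.fret_coupling, True,
         simulate.FRET_DONOR_BAND_NM),
        ("fret_null", "fret_excitation", 0.0, True, simulate.FRET_DONOR_BAND_NM),
        ("cd_consensus", "cd", config.cd_coupling, True, simulate.CD_DNA_BAND_NM),
        ("cd_nonconsensus", "cd", config.cd_coupling, False, simulate.CD_DNA_BAND_NM),
    ]
    for i, (name, kind, coupling, consensus, band) in enumerate(spec_runs):
        a, b, mix = simulate.simulate_spectra(
            coupling=coupling, kind=kind, seed=config.seed + 4000 + i,
            consensus=consensus,
        )
        diff = spectra.difference_spectrum(spectra.sum_spectra([a, b]), mix)
        score = spectra.band_enhancement(diff, band)
        for s, suffix in ((a, "a"), (b, "b"), (mix, "mix"), (diff, "diff")):
            _write(
                f"spectrum_{name}_{suffix}.csv",
                lambda p, s=s: spectra.write_spectrum_csv(s, p),
            )
        summary["spectra"][name] = {
            "kind": kind,
            "coupling": coupling,
            "consensus": consensus,
            **score.to_dict(),
        }

    summary["converged"] = bool(fit.converged)
    text = json.dumps(summary, indent=1, sort_keys=True)
    (outdir / "summary.json").write_text(text)
    manifest.append("summary.json")
    (outdir / "manifest.json").write_text(json.dumps(sorted(manifest), indent=1))
    _log(config, f"done; summary at {outdir / 'summary.json'}")
    return summary
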