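"""Pipeline orchestration and figure-style summary outputs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .epistasis import congruence_probability, motif_transition_matrix
from .fitness_map import GaussianMap, apply_map
from .generators import MismatchConfig, NKConfig, gen_mismatch, gen_nk, gen_two_locus
from .genotype_space import write_landscape
from .peaks import find_peaks, hoc_incongruence_sweep, nk_incongruence_sweep

__all__ = ["run_pipeline", "plot_sweep", "plot_transition_curves"]

_MOTIF_NAMES = ["no_sign", "simple_sign", "reciprocal_sign"]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _grid(config: dict) -> np.ndarray:
    if "w_opt_grid" in config:
        return np.asarray(config["w_opt_grid"], dtype=float)
    step = float(config.get("w_opt_step", 0.01))
    return np.round(np.arange(0.0, 1.0 + step / 2, step), 10)


def run_pipeline(config: dict, outdir) -> Path:
    """Execute the stages named in ``config["stages"]`` and write a manifest.

    Supported stages: ``generate`` (writes the configured model landscape
    and its fitness transform), ``magnitude_epistasis``, ``sign_epistasis``,
    ``peak_sweep``. All randomness flows from ``config["seed"]``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    grid = _grid(config)
    if grid.size == 0 or grid.min() < 0 or grid.max() > 1:
        raise ValueError("w_opt grid must be non-empty and lie within [0, 1]")
    n_reps = int(config.get("replicates", 10_000))
    if n_reps < 1:
        raise ValueError("replicates must be at least 1")
    outputs: list[str] = []

    for stage in config.get("stages", []):
        try:
            if stage == "generate":
                model = config.get("model", {"kind": "two_locus"})
                kind = model.get("kind", "two_locus")
                if kind == "two_locus":
                    land = gen_two_locus(seed)
                elif kind == "nk":
                    land = gen_nk(NKConfig(L=int(model["L"]), K=int(model["K"]), seed=seed))
                elif kind == "mismatch":
                    land = gen_mismatch(
                        MismatchConfig(
                            L=int(model.get("L", 8)),
                            a=int(model.get("a", 4)),
                            e=float(model.get("e", 0.05)),
                        )
                    )
                else:
                    raise ValueError(f"unknown model kind {kind!r}")
                write_landscape(land, outdir / "landscape.tsv")
                outputs.append("landscape.tsv")
                gmap = GaussianMap(
                    w_opt=float(config.get("w_opt", 0.5)), sigma=float(config.get("sigma", 1.0))
                )
                fit = apply_map(land, gmap)
                write_landscape(fit, outdir / "fitness.tsv")
                outputs.append("fitness.tsv")
                ps = find_peaks(fit)
                (outdir / "peaks.json").write_text(
                    json.dumps(
                        {
                            "n_peaks": ps.n_peaks,
                            "widths": ps.widths.tolist(),
                            "heights": ps.heights.tolist(),
                        },
                        indent=2,
                    )
                )
                outputs.append("peaks.json")
            elif stage == "magnitude_epistasis":
                df = congruence_probability(grid, float(config.get("sigma", 1.0)), n_reps, seed)
                df.to_csv(outdir / "magnitude_congruence.tsv", sep="\t", index=False)
                outputs.append("magnitude_congruence.tsv")
            elif stage == "sign_epistasis":
                matrix, counts = motif_transition_matrix(grid, n_reps, seed)
                for i, name in enumerate(_MOTIF_NAMES):
                    df = pd.DataFrame(
                        {
                            "w_opt": grid,
                            **{f"to_{to}": matrix[:, i, j] for j, to in enumerate(_MOTIF_NAMES)},
                            "n_squares": counts[:, i],
                        }
                    )
                    fname = f"sign_transitions_from_{name}.tsv"
                    df.to_csv(outdir / fname, sep="\t", index=False)
                    outputs.append(fname)
            elif stage == "peak_sweep":
                model = config.get("model", {"kind": "nk", "L": 5, "K": 1})
                L = int(model.get("L", 5))
                if model.get("kind") == "hoc":
                    df = hoc_incongruence_sweep(L, grid, n_reps, seed)
                else:
                    df = nk_incongruence_sweep(L, int(model.get("K", 0)), grid, n_reps, seed)
                df.to_csv(outdir / "peak_sweep.tsv", sep="\t", index=False)
                outputs.append("peak_sweep.tsv")
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": _config_hash(config),
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def _agg_backend():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_sweep(sweep_tsv, out_path) -> None:
    """Mean |p_f - p_gp| and change probabilities against w_opt."""
    plt = _agg_backend()
    df = pd.read_csv(sweep_tsv, sep="\t")
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    axes[0].plot(df["w_opt"], df["mean_abs_change"], "o-", ms=3)
    axes[0].set_xlabel(r"$w_{opt}$")
    axes[0].set_ylabel(r"$\langle |p_f - p_{gp}| \rangle$")
    for col, label in [("p_change", "change"), ("p_increase", "increase"), ("p_decrease", "decrease")]:
        axes[1].plot(df["w_opt"], df[col], "o-", ms=3, label=label)
    axes[1].set_xlabel(r"$w_{opt}$")
    axes[1].set_ylabel("probability")
    axes[1].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_transition_curves(tsv_paths, out_path) -> None:
    """Motif retention/transition probabilities against w_opt, one panel per origin."""
    plt = _agg_backend()
    fig, axes = plt.subplots(1, len(tsv_paths), figsize=(4 * len(tsv_paths), 3.5), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, path in zip(axes, tsv_paths):
        df = pd.read_csv(path, sep="\t")
        for name in _MOTIF_NAMES:
            ax.plot(df["w_opt"], df[f"to_{name}"], "o-", ms=3, label=name)
        ax.set_xlabel(r"$w_{opt}$")
        ax.set_title(Path(path).stem.replace("sign_transitions_from_", "from "))
    axes[0].set_ylabel("probability")
    axes[-1].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
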