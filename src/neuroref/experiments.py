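"""Seeded simulation drivers for the four re-referencing studies.

Each driver is a pure function of an :class:`ExperimentConfig` (including
its seed) and returns a tidy long-format :class:`pandas.DataFrame` with one
row per (condition, dipole, realization, metric).  The four studies:

* ``run_reference_comparison`` -- gRE of CzR/LMR/AR/REST over randomly
  sampled single dipoles, plus regional signed cRE for AR and REST;
* ``run_montage_density`` -- AR and REST accuracy across montage densities
  and REST head models (matched and mismatched);
* ``run_shift_experiment`` -- REST sensitivity to random and systematic
  electrode-position errors, with optional rigid headshape correction;
* ``run_artifact_experiment`` -- artifact reduction index of LMR/AR/REST
  for patch, homogeneous and random artifact topographies.

Truth maps are always the infinity-referenced potentials of the truth model
evaluated at the *unperturbed* electrode positions; electrode-position
noise corrupts only the leadfield used to build the REST operator, because
misdigitised coordinates distort the model, not the physical recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ValidationError
from .forward import (
    HeadModel,
    Leadfield,
    SourceGrid,
    build_leadfield,
    make_source_grid,
    sample_dipoles,
)
from .metrics import ari, cre, gre, make_artifact, make_regions
from .montage import HeadShape, Montage, make_standard_montage, perturb_positions, rigid_align
from .reref import make_ar, make_czr, make_lmr, make_rest

__all__ = [
    "ExperimentConfig",
    "run_reference_comparison",
    "run_montage_density",
    "run_shift_experiment",
    "run_artifact_experiment",
    "summarize",
    "write_report",
]

ORIENTATION_AXES = {"x": 0, "y": 1, "z": 2}

#: columns that identify a single measurement (everything except value)
KEY_COLUMNS = [
    "experiment", "method", "montage", "model", "orientation",
    "dipole", "realization", "magnitude", "kind", "metric",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared configuration for the experiment drivers.

    Defaults reproduce the study conditions: 100 random dipoles, x/y/z unit
    orientations, the 256-channel montage for the single-montage studies,
    all four montages for the density study, shifts of 1/2/4/8 mm with 10
    realizations, and a concentric-shell truth model (the realistic-BEM
    truth condition is enabled by passing an imported leadfield).
    """

    seed: int = 0
    n_dipoles: int = 100
    orientations: tuple[str, ...] = ("x", "y", "z")
    montage: str = "dense_256"
    montages: tuple[str, ...] = ("ten20_21", "ten10_71", "dense_128", "dense_256")
    truth_model: HeadModel = field(default_factory=HeadModel.sphere3)
    rest_model: HeadModel = field(default_factory=HeadModel.sphere3)
    rest_models: tuple[str, ...] = ("sphere1", "sphere3")
    grid_spacing_mm: float = 10.0
    n_terms: int = 100
    pinv_tol: float = 1e-8
    shift_magnitudes_mm: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    n_realizations: int = 10
    artifact_kinds: tuple[str, ...] = ("patch", "homogeneous", "random")
    external_leadfield: Leadfield | None = None

    def __post_init__(self) -> None:
        if self.n_dipoles < 1:
            raise ValidationError("n_dipoles must be >= 1")
        for m in (self.montage, *self.montages):
            if m not in ("ten20_21", "ten10_71", "dense_128", "dense_256"):
                raise ValidationError(f"unknown montage name {m!r}")
        for o in self.orientations:
            if o not in ORIENTATION_AXES:
                raise ValidationError(f"unknown orientation {o!r}")


def _child_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2**31))


def _named_model(name: str, like: HeadModel) -> HeadModel:
    if name == "sphere1":
        return HeadModel.sphere1(like.scalp_radius_mm)
    if name == "sphere3":
        return HeadModel.sphere3(like.scalp_radius_mm)
    raise ValidationError(f"unknown head model name {name!r}")


def _truth_maps(
    model: HeadModel, montage: Montage, positions: np.ndarray, n_terms: int
) -> np.ndarray:
    """Infinity-referenced maps of unit x/y/z dipoles: (n_dipoles, 3, N)."""
    grid = SourceGrid(positions=positions, spacing_mm=0.0)
    lf = build_leadfield(model, montage, grid, n_terms=n_terms)
    n = montage.n_channels
    return lf.gain.T.reshape(positions.shape[0], 3, n)


def _rest_from_config(config: ExperimentConfig, montage: Montage, model: HeadModel):
    if config.external_leadfield is not None:
        lf = config.external_leadfield
        if lf.n_channels != montage.n_channels:
            raise ValidationError(
                f"imported leadfield has {lf.n_channels} channels, montage has "
                f"{montage.n_channels}"
            )
        return make_rest(lf, config.pinv_tol)
    grid = make_source_grid(model, spacing_mm=config.grid_spacing_mm)
    lf = build_leadfield(model, montage, grid, n_terms=config.n_terms)
    return make_rest(lf, config.pinv_tol)


def _finish(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for col in KEY_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df[KEY_COLUMNS + ["value"]]
    if df.duplicated(subset=KEY_COLUMNS).any():
        raise ValidationError("duplicate key tuples in result table")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ValidationError("non-finite values in result table")
    return df


# ---------------------------------------------------------------------------
# study 1: reference comparison (gRE per method, regional cRE)


def run_reference_comparison(config: ExperimentConfig) -> pd.DataFrame:
    montage = make_standard_montage(config.montage)
    dipoles = sample_dipoles(config.truth_model, config.n_dipoles, _child_seed(config.seed, 1))
    truth = _truth_maps(config.truth_model, montage, dipoles, config.n_terms)
    operators = {
        "CzR": make_czr(montage),
        "LMR": make_lmr(montage),
        "AR": make_ar(montage.n_channels),
        "REST": _rest_from_config(config, montage, config.rest_model),
    }
    regions = make_regions(montage)
    rows: list[dict] = []
    for method, op in operators.items():
        for j in range(config.n_dipoles):
            for orient in config.orientations:
                v = truth[j, ORIENTATION_AXES[orient]]
                v_re = op.matrix @ v
                rows.append(dict(
                    experiment="reference_comparison", method=method,
                    montage=config.montage, model=config.truth_model.kind,
                    orientation=orient, dipole=j, metric="gre",
                    value=gre(v_re, v),
                ))
                if method in ("AR", "REST"):
                    for rname, idx in regions.regions.items():
                        vals = [cre(v_re, v, i) for i in idx]
                        used = [x for x in vals if x is not None]
                        if used:
                            rows.append(dict(
                                experiment="reference_comparison", method=method,
                                montage=config.montage, model=config.truth_model.kind,
                                orientation=orient, dipole=j,
                                metric=f"cre_{rname}", value=float(np.mean(used)),
                            ))
    return _finish(rows)


# ---------------------------------------------------------------------------
# study 2: montage density x head model


def run_montage_density(config: ExperimentConfig) -> pd.DataFrame:
    dipoles = sample_dipoles(config.truth_model, config.n_dipoles, _child_seed(config.seed, 1))
    rows: list[dict] = []
    for mname in config.montages:
        montage = make_standard_montage(mname)
        truth = _truth_maps(config.truth_model, montage, dipoles, config.n_terms)
        ops = {("AR", ""): make_ar(montage.n_channels)}
        for rest_name in config.rest_models:
            model = _named_model(rest_name, config.truth_model)
            ops[("REST", rest_name)] = _rest_from_config(
                replace(config, external_leadfield=None), montage, model
            )
        if config.external_leadfield is not None and \
                config.external_leadfield.n_channels == montage.n_channels:
            ops[("REST", "imported")] = make_rest(config.external_leadfield, config.pinv_tol)
        for (method, model_name), op in ops.items():
            for j in range(config.n_dipoles):
                for orient in config.orientations:
                    v = truth[j, ORIENTATION_AXES[orient]]
                    rows.append(dict(
                        experiment="montage_density", method=method, montage=mname,
                        model=model_name, orientation=orient, dipole=j,
                        metric="gre", value=gre(op.matrix @ v, v),
                    ))
    return _finish(rows)


# ---------------------------------------------------------------------------
# study 3: electrode-position noise


SHIFT_CONDITIONS = ("RS", "SSu", "SSc")  # random / systematic / systematic+corrected


def run_shift_experiment(config: ExperimentConfig) -> pd.DataFrame:
    if any(m < 0 for m in config.shift_magnitudes_mm):
        raise ValidationError("shift magnitudes must be non-negative")
    montage = make_standard_montage(config.montage)
    headshape = HeadShape(points=montage.positions)
    dipoles = sample_dipoles(config.truth_model, config.n_dipoles, _child_seed(config.seed, 1))
    truth = _truth_maps(config.truth_model, montage, dipoles, config.n_terms)
    rest_true = _rest_from_config(config, montage, config.rest_model)

    def gre_per_case(op) -> np.ndarray:
        out = np.empty((config.n_dipoles, len(config.orientations)))
        for j in range(config.n_dipoles):
            for k, orient in enumerate(config.orientations):
                v = truth[j, ORIENTATION_AXES[orient]]
                out[j, k] = gre(op.matrix @ v, v)
        return out

    base = gre_per_case(rest_true)
    rows: list[dict] = []
    for mag_i, mag in enumerate(config.shift_magnitudes_mm):
        for real in range(config.n_realizations):
            seed_r = _child_seed(config.seed, 2, mag_i, real)
            perturbed = {
                "RS": perturb_positions(montage, "random", mag, seed_r),
                "SSu": perturb_positions(montage, "systematic", mag, seed_r),
            }
            perturbed["SSc"] = (
                rigid_align(perturbed["SSu"], headshape) if mag > 0 else perturbed["SSu"]
            )
            for cond, pert in perturbed.items():
                op = _rest_from_config(config, pert, config.rest_model)
                delta = gre_per_case(op) - base
                for j in range(config.n_dipoles):
                    for k, orient in enumerate(config.orientations):
                        rows.append(dict(
                            experiment="shift_noise", method="REST",
                            montage=config.montage, model=config.rest_model.kind,
                            orientation=orient, dipole=j, realization=real,
                            magnitude=mag, kind=cond, metric="delta_gre",
                            value=delta[j, k],
                        ))
    return _finish(rows)


# ---------------------------------------------------------------------------
# study 4: artifact sensitivity


def run_artifact_experiment(config: ExperimentConfig) -> pd.DataFrame:
    montage = make_standard_montage(config.montage)
    operators = {
        "LMR": make_lmr(montage),
        "AR": make_ar(montage.n_channels),
        "REST": _rest_from_config(config, montage, config.rest_model),
    }
    rows: list[dict] = []
    for kind in config.artifact_kinds:
        pattern = make_artifact(kind, montage, seed=_child_seed(config.seed, 3))
        for method, op in operators.items():
            rows.append(dict(
                experiment="artifact_sensitivity", method=method,
                montage=config.montage, model=config.rest_model.kind,
                kind=kind, metric="ari", value=ari(op, pattern),
            ))
    return _finish(rows)


# ---------------------------------------------------------------------------
# summaries and reports


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error (sd / sqrt(n)) per experimental condition.

    Averaging pools dipoles and realizations within each condition; groups
    with a single observation report a zero standard error and are flagged.
    """
    if table.empty:
        raise ValidationError("cannot summarize an empty result table")
    group_cols = [c for c in KEY_COLUMNS if c not in ("dipole", "realization")]
    groups = table.groupby(group_cols, dropna=False, sort=False)["value"]
    out = groups.agg(["mean", "std", "count"]).reset_index()
    out = out.rename(columns={"count": "n"})
    out["se"] = np.where(out["n"] > 1, out["std"].fillna(0.0) / np.sqrt(out["n"]), 0.0)
    out["se_degenerate"] = out["n"] == 1
    return out.drop(columns=["std"])


def write_report(table: pd.DataFrame, out_dir, config: ExperimentConfig | None = None) -> dict:
    """Write results.csv, summary.json and run-metadata.json to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / "results.csv", index=False)
    summary = summarize(table)
    summary_records = summary.to_dict(orient="records")
    (out_dir / "summary.json").write_text(json.dumps(summary_records, indent=1))
    meta = {
        "package": "neuroref",
        "version": __version__,
        "n_rows": int(len(table)),
        "experiments": sorted(table["experiment"].unique().tolist()),
    }
    if config is not None:
        meta["config"] = {
            "seed": config.seed,
            "n_dipoles": config.n_dipoles,
            "montage": config.montage,
            "montages": list(config.montages),
            "truth_model": config.truth_model.describe(),
            "rest_model": config.rest_model.describe(),
            "grid_spacing_mm": config.grid_spacing_mm,
            "n_terms": config.n_terms,
            "pinv_tol": config.pinv_tol,
            "shift_magnitudes_mm": list(config.shift_magnitudes_mm),
            "n_realizations": config.n_realizations,
        }
    (out_dir / "run-metadata.json").write_text(json.dumps(meta, indent=1))
    return meta
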