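"""Crossed-design simulation study: generation, fitting, evaluation.

The benchmark crosses sample size, dimensionality, number of components,
signal strength (VAF) and sparsity proportion, generates replicate datasets
under each condition, fits the applicable sparse PCA methods with the true
number of components and the true sparsity level (oracle tuning — the
protocol isolates method differences from tuning differences), and scores
them after component alignment.

Three condition types pair generators with method families:

- type I (matching): sparse-loadings data -> loadings methods
  (varimax, simplimax, spca-rsvd); sparse-weights data -> weights methods
  (spca, pathspca, gpower).  Measures: SRE, MR, PEV.
- type II (double sparsity): the doubly sparse generator analyzed by both
  families, each under its own scenario.  Measures: SRE, MR, PEV.
- type III (mismatch): the families are swapped across generators and
  recovery is scored by Tucker congruence against the *other* parameter
  matrix (estimated loadings vs true weights and vice versa).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import (
    MetricsRecord,
    align_components,
    apply_alignment,
    cossim,
    index_of_sparseness,
    mr,
    pev,
    sre,
)
from .pca_core import ComponentModel, as_matrix, pca_fit, truncated_svd
from .rotation import simplimax, threshold_to_sparsity, varimax
from .rsvd import PenaltySpec, spca_rsvd_fit
from .synthetic import GeneratedDataset, condition_seed, generate
from .weights import gpower_fit, pathspca_fit, spca_zou_fit

__all__ = [
    "ConditionSpec",
    "StudyResult",
    "LOADINGS_METHODS",
    "WEIGHTS_METHODS",
    "build_design",
    "fit_method",
    "run_condition",
    "run_study",
    "tune_sparsity_by_is",
    "cardinality_from_ps",
    "default_config",
]

logger = logging.getLogger("spcakit.study")

LOADINGS_METHODS = ("varimax", "simplimax", "spca-rsvd")
WEIGHTS_METHODS = ("spca", "pathspca", "gpower")

#: Default factor grids (full crossed design).
FULL_GRIDS = {
    "I": [100, 500],
    "J": [10, 100, 1000],
    "K": [2, 3],
    "vaf": [0.8, 0.95, 1.0],
    "ps": [0.0, 0.5, 0.8],
}
#: Sparsity levels for the doubly sparse regime (disjoint supports need
#: high sparsity to avoid overlap).
DOUBLE_PS = [0.7, 0.8, 0.9]


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the crossed design, for one replicate."""

    regime: str
    I: int
    J: int
    K: int
    vaf: float
    ps: float
    replicate: int
    seed: int


@dataclass
class StudyResult:
    """Long table of metric values plus a per-cell summary."""

    long: pd.DataFrame
    summary: pd.DataFrame


def cardinality_from_ps(ps: float, J: int) -> int:
    """Nonzeros per component implied by a sparsity proportion."""
    return max(1, int(round((1.0 - ps) * J)))


def build_design(
    grids: dict | None = None,
    reps: int = 100,
    regime: str = "alg1-sparseP",
    master_seed: int = 0,
) -> list[ConditionSpec]:
    """Fully crossed design: Cartesian product of factor levels times reps.

    Seeds are assigned per dataset by a stable hash of the condition, so a
    subset of the design sees the same data as the full design.
    """
    grids = dict(FULL_GRIDS if grids is None else grids)
    if regime == "alg3-double" and "ps" not in (grids or {}):
        grids["ps"] = DOUBLE_PS
    for name in ("I", "J", "K", "vaf", "ps"):
        if not grids.get(name):
            raise ValueError(f"empty factor grid: {name}")
    conditions = []
    for I, J, K, vaf, ps in itertools.product(
        grids["I"], grids["J"], grids["K"], grids["vaf"], grids["ps"]
    ):
        for rep in range(1, reps + 1):
            seed = condition_seed(regime, I, J, K, vaf, ps, rep, master_seed)
            conditions.append(
                ConditionSpec(
                    regime=regime, I=I, J=J, K=K, vaf=vaf, ps=ps,
                    replicate=rep, seed=seed,
                )
            )
    return conditions


def _unit_score_pca(X, K: int):
    """PCA with orthonormal scores T = U and scale-carrying loadings P = V D."""
    svd = truncated_svd(X, K)
    return svd.U.copy(), svd.V * svd.D


def fit_method(
    name: str,
    X,
    K: int,
    ps: float,
    seed: int | None = 0,
) -> tuple[ComponentModel, np.ndarray]:
    """Fit one sparse PCA method at a given sparsity proportion.

    Returns the fitted model and the estimated zero mask of the matrix the
    method sparsifies (loadings or weights).
    """
    values = as_matrix(X)
    J = values.shape[1]
    r = cardinality_from_ps(ps, J)
    if name == "varimax":
        T, P = _unit_score_pca(values, K)
        rot = varimax(P, scores=T) if K > 1 else None
        L = rot.rotated_loadings if rot else P
        S = rot.rotated_scores if rot else T
        thr = threshold_to_sparsity(L, ps)
        model = ComponentModel(
            scores=S, loadings=thr.loadings, weights=None,
            n_components=K, method="varimax",
        )
        return model, thr.zero_mask
    if name == "simplimax":
        T, P = _unit_score_pca(values, K)
        m = int(np.floor(ps * J * K))
        rot = simplimax(P, m, scores=T, seed=seed)
        thr = threshold_to_sparsity(rot.rotated_loadings, ps)
        model = ComponentModel(
            scores=rot.rotated_scores, loadings=thr.loadings, weights=None,
            n_components=K, method="simplimax",
        )
        return model, thr.zero_mask
    if name == "spca-rsvd":
        model = spca_rsvd_fit(values, K, PenaltySpec(mode="cardinality", cardinality=r))
        return model, model.loadings == 0
    if name == "spca":
        if ps == 0:
            model = spca_zou_fit(values, K, PenaltySpec(mode="lasso", lam=0.0))
        else:
            model = spca_zou_fit(
                values, K, PenaltySpec(mode="cardinality", cardinality=r)
            )
        return model, model.weights == 0
    if name == "pathspca":
        model = pathspca_fit(values, K, r)
        return model, model.weights == 0
    if name == "gpower":
        model = gpower_fit(values, K, PenaltySpec(mode="cardinality", cardinality=r))
        return model, model.weights == 0
    raise ValueError(f"unknown method {name!r}")


def _sparse_estimate(model: ComponentModel) -> np.ndarray:
    """The matrix the method sparsifies: W if present, else P."""
    return model.weights if model.weights is not None else model.loadings


def evaluate_model(
    dataset: GeneratedDataset,
    model: ComponentModel,
    zero_mask_est: np.ndarray,
    condition_type: str,
) -> MetricsRecord:
    """Score one fitted model against the generating truth.

    Components are aligned on the condition's sparse target (min-SRE for
    matched structure, max mean cosine for mismatched structure); scores and
    masks inherit the alignment.
    """
    estimate = _sparse_estimate(model)
    truth = dataset.sparse_target
    true_mask = dataset.sparse_zero_mask
    objective = "max-cossim" if condition_type == "III" else "min-sre"
    perm, signs = align_components(estimate, truth, objective=objective)
    est_aligned = apply_alignment(estimate, perm, signs)
    scores_aligned = apply_alignment(model.scores, perm, signs)
    mask_aligned = np.asarray(zero_mask_est)[:, list(perm)]

    rec = MetricsRecord(method=model.method, alignment=(perm, tuple(signs)))
    rec.pev = pev(dataset.X, model.scores, model.loadings)
    if dataset.ps > 0:
        rec.mr = mr(true_mask, mask_aligned)
    if condition_type == "III":
        rec.cossim_crossparam = cossim(est_aligned, truth)
        rec.cossim_scores = cossim(scores_aligned, dataset.T_true)
    else:
        target_sre = sre(est_aligned, truth)
        if model.weights is not None:
            rec.sre_weights = target_sre
        else:
            rec.sre_loadings = target_sre
        rec.sre_scores = sre(scores_aligned, dataset.T_true)
    return rec


#: (condition_type, data regime) -> method family analyzing that data.
PAIRINGS = {
    ("I", "alg1-sparseP"): LOADINGS_METHODS,
    ("I", "alg2-sparseW"): WEIGHTS_METHODS,
    ("II", "alg3-double"): LOADINGS_METHODS + WEIGHTS_METHODS,
    ("III", "alg2-sparseW"): LOADINGS_METHODS,
    ("III", "alg1-sparseP"): WEIGHTS_METHODS,
}


def run_condition(
    cond: ConditionSpec,
    condition_type: str,
    methods: tuple[str, ...] | None = None,
    oracle_tuning: bool = True,
) -> dict[str, MetricsRecord]:
    """Generate one dataset and score every applicable method on it.

    With ``oracle_tuning`` (the study protocol) each method receives the
    true number of components and the true sparsity level.  Failures are
    recorded as failed records, not raised.
    """
    if methods is None:
        methods = PAIRINGS[(condition_type, cond.regime)]
    records: dict[str, MetricsRecord] = {}
    datasets: dict[str, GeneratedDataset] = {}
    for name in methods:
        family_loadings = name in LOADINGS_METHODS
        if cond.regime == "alg3-double":
            scenario = "sparse-P" if family_loadings else "sparse-W"
        else:
            scenario = "sparse-P"
        if scenario not in datasets:
            datasets[scenario] = generate(
                cond.regime, cond.I, cond.J, cond.K, cond.vaf, cond.ps,
                seed=cond.seed, scenario=scenario,
            )
        dataset = datasets[scenario]
        ps = cond.ps if oracle_tuning else 0.0
        try:
            model, zero_mask = fit_method(name, dataset.X, cond.K, ps, seed=cond.seed)
            records[name] = evaluate_model(dataset, model, zero_mask, condition_type)
        except Exception as exc:  # noqa: BLE001 - sweep must survive failures
            logger.warning("condition %s method %s failed: %s", cond, name, exc)
            records[name] = MetricsRecord(method=name, failed=True)
    return records


LONG_COLUMNS = [
    "regime", "I", "J", "K", "vaf", "ps", "replicate",
    "condition_type", "method", "metric", "value",
]


def default_config() -> dict:
    """Desk-scale configuration: the full factor structure at reduced size.

    Excludes the largest dimensionalities and runs 10 replicates so the
    whole sweep completes quickly at one CPU; the grids can be overridden
    (``full=True`` restores the complete crossed design).
    """
    return {
        "design": {
            "I": [100],
            "J": [10, 100],
            "K": [2],
            "vaf": [0.8],
            "ps": [0.5, 0.8],
        },
        "condition_types": ["I", "II", "III"],
        "reps": 10,
        "seed": 0,
        "methods": None,
    }


def run_study(config: dict | None = None) -> StudyResult:
    """Run the configured subset of the crossed design and summarize it.

    Returns a long table with one row per (condition, method, metric) and a
    summary of per-cell medians and quartiles.  Fully reproducible from the
    configuration and master seed.
    """
    cfg = default_config()
    if config:
        cfg.update(config)
    rows = []
    for ctype in cfg["condition_types"]:
        regimes = [r for (t, r) in PAIRINGS if t == ctype]
        for regime in regimes:
            grids = dict(cfg["design"])
            if regime == "alg3-double":
                grids["ps"] = [p for p in DOUBLE_PS if p in grids["ps"]] or DOUBLE_PS[:1]
            conditions = build_design(
                grids, reps=cfg["reps"], regime=regime, master_seed=cfg["seed"]
            )
            for cond in conditions:
                methods = cfg.get("methods")
                if methods is not None:
                    methods = tuple(
                        m for m in PAIRINGS[(ctype, regime)] if m in methods
                    )
                    if not methods:
                        continue
                records = run_condition(cond, ctype, methods=methods)
                for name, rec in records.items():
                    base = {
                        "regime": cond.regime, "I": cond.I, "J": cond.J,
                        "K": cond.K, "vaf": cond.vaf, "ps": cond.ps,
                        "replicate": cond.replicate, "condition_type": ctype,
                        "method": name,
                    }
                    if rec.failed:
                        rows.append({**base, "metric": "failed", "value": 1.0})
                        continue
                    rows.append({**base, "metric": "failed", "value": 0.0})
                    for metric, value in rec.as_dict().items():
                        rows.append({**base, "metric": metric, "value": value})
    long = pd.DataFrame(rows, columns=LONG_COLUMNS)
    keys = [c for c in LONG_COLUMNS if c not in ("replicate", "value")]
    summary = (
        long.groupby(keys, dropna=False)["value"]
        .agg(median="median", q1=lambda s: s.quantile(0.25),
             q3=lambda s: s.quantile(0.75), n="count")
        .reset_index()
    )
    return StudyResult(long=long, summary=summary)


def tune_sparsity_by_is(
    X,
    K: int,
    method: str = "spca-rsvd",
    ps_grid=None,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Tune the sparsity proportion by maximizing the index of sparseness.

    Fits the method at each grid value, computes
    ``IS = PEV_sparse * PEV_pca * PS`` and returns the argmax together with
    the IS and PEV curves.
    """
    values = as_matrix(X)
    if ps_grid is None:
        ps_grid = np.round(np.arange(0.0, 0.95, 0.05), 2)
    base = pca_fit(values, K)
    pev_pca = pev(values, base.scores, base.loadings)
    rows = []
    n_ok = 0
    for ps in ps_grid:
        try:
            model, _ = fit_method(method, values, K, float(ps), seed=seed)
            pev_sparse = pev(values, model.scores, model.loadings)
            n_ok += 1
        except Exception as exc:  # noqa: BLE001
            logger.warning("tuning fit failed at ps=%s: %s", ps, exc)
            pev_sparse = math.nan
        rows.append(
            {
                "ps": float(ps),
                "pev_sparse": pev_sparse,
                "is_value": index_of_sparseness(pev_sparse, pev_pca, float(ps))
                if not math.isnan(pev_sparse)
                else math.nan,
            }
        )
    if n_ok == 0:
        raise RuntimeError("every fit on the sparsity grid failed")
    curves = pd.DataFrame(rows)
    curves["pev_pca"] = pev_pca
    best_ps = float(curves.loc[curves["is_value"].idxmax(), "ps"])
    return best_ps, curves
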