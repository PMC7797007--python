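"""Full-factorial e' sweeps and quadratic response-surface modelling.

Protocol optimization treats stenosis estimation precision (the fractional SD,
i.e. 1/e') as the response of a designed experiment over patient factors
(vessel diameter, stenosis, velocity, plaque material, luminal contrast) and
protocol factors (pixel size, noise magnitude, rotation time, dual-source
acquisition, TTF f50).  The design is swept with the estimator engine, the
response fit with an ordinary least-squares model containing intercept,
linear, pairwise-interaction and squared terms, and the fit interrogated via
partial-dependence curves and single-factor slice predictions with confidence
bands.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cases import CaseSpec, ScannerSpec
from .estimator import EngineConfig, compute_case_eprime

logger = logging.getLogger(__name__)

__all__ = [
    "FactorGrid",
    "FittedModel",
    "factorial_grid",
    "run_sweep",
    "fit_response_model",
    "partial_dependence",
    "predict_slice",
]

#: Factor name -> CaseSpec/ScannerSpec assignment used by ``run_sweep``.
_CONTINUOUS_CASE_FACTORS = {
    "diameter": "diameter_mm",
    "stenosis_pct": "stenosis_severity_pct",
    "velocity": "velocity_mm_s",
    "contrast": "lumen_enhancement",
}
_CONTINUOUS_SCANNER_FACTORS = {
    "pixel_size": "pixel_size_mm",
    "noise_sigma": "sigma_hu",
    "rotation_time": "rotation_time_s",
    "ttf_f50": "ttf_f50",
}

#: Clinically relevant default design (three levels per continuous factor).
DEFAULT_FACTOR_CONFIG: dict[str, list] = {
    "diameter": [1.5, 3.25, 5.0],
    "stenosis_pct": [30.0, 50.0, 70.0],
    "velocity": [15.0, 25.0, 35.0],
    "plaque_material": ["noncalcified", "mixed", "calcified"],
    "contrast": [300.0, 450.0, 600.0],
    "pixel_size": [0.35, 0.45, 0.55],
    "noise_sigma": [15.0, 30.0, 45.0],
    "rotation_time": [0.25, 0.30, 0.35],
    "dual_source": ["off", "on"],
    "ttf_f50": [0.32, 0.42, 0.52],
}


@dataclass
class FactorGrid:
    """Full-factorial design over named factors.

    ``design`` holds one row per level combination in deterministic order
    (factors sorted by name, levels in the order given).
    """

    factors: dict[str, list]
    design: pd.DataFrame

    @property
    def n_rows(self) -> int:
        return len(self.design)


def factorial_grid(factor_config: dict[str, list]) -> FactorGrid:
    """Cartesian product of the factor levels with deterministic row order."""
    if not factor_config:
        raise ValueError("at least one factor required")
    for name, levels in factor_config.items():
        if len(levels) == 0:
            raise ValueError(f"factor {name!r} has no levels")
    names = sorted(factor_config)
    rows = list(itertools.product(*(factor_config[n] for n in names)))
    design = pd.DataFrame(rows, columns=names)
    return FactorGrid(factors={n: list(factor_config[n]) for n in names},
                      design=design)


def _case_from_row(row: pd.Series, base_engine: EngineConfig) -> CaseSpec:
    scanner = ScannerSpec()
    case_kwargs: dict = {}
    for name, val in row.items():
        if name in _CONTINUOUS_CASE_FACTORS:
            case_kwargs[_CONTINUOUS_CASE_FACTORS[name]] = float(val)
        elif name in _CONTINUOUS_SCANNER_FACTORS:
            setattr(scanner, _CONTINUOUS_SCANNER_FACTORS[name], float(val))
        elif name == "plaque_material":
            case_kwargs["plaque_material"] = str(val)
        elif name == "dual_source":
            scanner.n_sources = 2 if str(val) == "on" else 1
        else:
            raise KeyError(f"unknown sweep factor {name!r}")
    return CaseSpec(case_id="sweep", scanner=scanner, **case_kwargs)


def run_sweep(
    grid: FactorGrid,
    engine: EngineConfig | None = None,
    n_instances: int = 500,
    seed: int = 0,
    subsample: int | None = None,
) -> pd.DataFrame:
    """Compute e' and precision for every design row.

    Per-row seeds are spawned from the root seed, so reruns (and row-subsampled
    runs) are reproducible.  Degenerate rows (CNR or velocity out of regime)
    are flagged, not dropped; their precision is NaN.
    """
    engine = engine or EngineConfig()
    design = grid.design
    if subsample is not None and subsample < len(design):
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(design), size=subsample, replace=False))
        design = design.iloc[keep]
    root = np.random.SeedSequence(seed)
    children = root.spawn(grid.n_rows)  # one stream per design row, stable ids
    records = []
    for pos, (ridx, row) in enumerate(design.iterrows()):
        case = _case_from_row(row, engine)
        res = compute_case_eprime(
            case, n_instances=n_instances, seed=children[int(ridx)], engine=engine
        )
        rec = dict(row)
        degenerate = res.flags.degenerate_cnr or res.flags.degenerate_velocity
        rec.update(
            row_id=int(ridx),
            e_prime=res.e_prime,
            precision=(math.nan if degenerate or not math.isfinite(res.e_prime)
                       else 1.0 / res.e_prime),
            degenerate=degenerate,
            zero_variance=res.flags.zero_variance,
        )
        records.append(rec)
        if (pos + 1) % 50 == 0:
            logger.info("sweep progress: %d/%d rows", pos + 1, len(design))
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# response-surface fitting


@dataclass
class FittedModel:
    """OLS response-surface fit of precision on the design factors."""

    terms: list[str]
    coefficients: dict[str, float]
    rmse: float
    r_squared: float
    response: str
    continuous: list[str]
    categorical: dict[str, list]
    factor_ranges: dict[str, tuple[float, float]]
    results: object = field(repr=False, default=None)  # statsmodels results

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(table, self.terms, self.categorical)
        return np.asarray(self.results.predict(X))


def _term_columns(
    table: pd.DataFrame,
    continuous: list[str],
    categorical: dict[str, list],
) -> pd.DataFrame:
    """All candidate columns: linear, dummies, squares, pairwise products."""
    cols: dict[str, np.ndarray] = {}
    for f in continuous:
        cols[f] = table[f].to_numpy(dtype=float)
    for f, levels in categorical.items():
        for lev in levels[1:]:  # first level is the reference
            cols[f"{f}[{lev}]"] = (table[f] == lev).to_numpy(dtype=float)
    base = list(cols)
    for f in continuous:
        cols[f"{f}^2"] = cols[f] ** 2
    for a, b in itertools.combinations(base, 2):
        cols[_canonical_term(f"{a}:{b}")] = cols[a] * cols[b]
    return pd.DataFrame(cols, index=table.index)


def _canonical_term(term: str) -> str:
    """Interaction terms are order-free: operands are sorted alphabetically."""
    if ":" in term:
        return ":".join(sorted(term.split(":")))
    return term


def _design_matrix(table: pd.DataFrame, terms: list[str],
                   categorical: dict[str, list]) -> pd.DataFrame:
    all_cols = _term_columns(table, continuous=_infer_continuous(terms),
                             categorical=categorical)
    X = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)
    for t in terms:
        if t == "Intercept":
            continue
        X[t] = all_cols[_canonical_term(t)]
    return X


def _infer_continuous(terms: list[str]) -> list[str]:
    out = []
    for t in terms:
        if t == "Intercept":
            continue
        for part in t.replace("^2", "").split(":"):
            name = part.split("[")[0]
            if "[" not in part and name not in out:
                out.append(name)
    return out


def fit_response_model(
    table: pd.DataFrame,
    term_spec: list[str] | None = None,
    response: str = "precision",
    prune_alpha: float = 0.01,
) -> FittedModel:
    """Least-squares quadratic response-surface fit.

    With ``term_spec=None`` the candidate set is the full quadratic (linear +
    squared terms for continuous factors, dummy-coded categoricals, all
    pairwise interactions), pruned by backward elimination at the configured
    significance level.  An explicit ``term_spec`` (list of term names such as
    ``["noise_sigma", "noise_sigma^2"]``) is fit as-is.  Degenerate design rows
    are excluded.
    """
    data = table[np.isfinite(table[response])].copy()
    factor_names = [c for c in table.columns
                    if c not in (response, "e_prime", "precision", "row_id",
                                 "degenerate", "zero_variance", "flags")]
    continuous = [f for f in factor_names
                  if pd.api.types.is_numeric_dtype(table[f])]
    # appearance order: the first level observed is the reference level
    categorical = {f: list(pd.unique(table[f]))
                   for f in factor_names if f not in continuous}
    y = data[response].to_numpy(dtype=float)

    all_cols = _term_columns(data, continuous, categorical)
    if term_spec is not None:
        terms = ["Intercept"] + [
            _canonical_term(t) for t in term_spec if t != "Intercept"
        ]
    else:
        terms = ["Intercept"] + list(all_cols.columns)

    def _fit(term_list: list[str]):
        X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
        for t in term_list:
            if t != "Intercept":
                X[t] = all_cols[t]
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            raise ValueError(
                f"rank-deficient design ({rank} < {X.shape[1]}); "
                f"collinear terms among {list(X.columns)}"
            )
        if len(data) <= X.shape[1]:
            raise ValueError("more terms than design rows")
        return sm.OLS(y, X).fit(), X

    res, X = _fit(terms)
    if term_spec is None and prune_alpha is not None:
        if res.ssr / max(len(y), 1) < 1e-20:
            # perfect fit: p-values are undefined, prune by coefficient size
            scale = np.abs(res.params).max()
            terms = ["Intercept"] + [
                t for t in terms[1:] if abs(res.params[t]) > 1e-8 * max(scale, 1.0)
            ]
            res, X = _fit(terms)
        else:
            while len(terms) > 1:
                pvals = res.pvalues.drop("Intercept")
                worst = pvals.idxmax()
                if pvals[worst] < prune_alpha:
                    break
                terms = [t for t in terms if t != worst]
                res, X = _fit(terms)

    rmse = float(np.sqrt(res.ssr / len(y)))
    ranges = {f: (float(data[f].min()), float(data[f].max())) for f in continuous}
    return FittedModel(
        terms=list(X.columns),
        coefficients={t: float(res.params[t]) for t in X.columns},
        rmse=rmse,
        r_squared=float(res.rsquared),
        response=response,
        continuous=continuous,
        categorical=categorical,
        factor_ranges=ranges,
        results=res,
    )


def partial_dependence(
    table: pd.DataFrame, factor: str, response: str = "precision"
) -> pd.DataFrame:
    """Mean response per level of one factor, marginalised over all others.

    On a full-factorial (balanced) design the plain group-by mean weighs every
    other-factor combination equally.
    """
    if factor not in table.columns:
        raise KeyError(f"factor {factor!r} not in table")
    data = table[np.isfinite(table[response])]
    curve = (
        data.groupby(factor, sort=True)[response]
        .mean()
        .reset_index()
        .rename(columns={response: "mean_response"})
    )
    return curve


def predict_slice(
    model: FittedModel,
    at_values: dict,
    vary_factor: str,
    n_points: int = 50,
    levels: list | None = None,
) -> pd.DataFrame:
    """Predicted response along one factor with the others held constant.

    Returns the prediction and its 95% confidence band (from the coefficient
    covariance) per point.  Values outside the fitted design range trigger a
    warning, not an error.
    """
    missing = [f for f in model.continuous + list(model.categorical)
               if f != vary_factor and f not in at_values]
    if missing:
        raise ValueError(f"at_values must fix all other factors; missing {missing}")
    if vary_factor in model.continuous:
        lo, hi = model.factor_ranges[vary_factor]
        xs = np.linspace(lo, hi, n_points) if levels is None else np.asarray(levels, float)
        if levels is not None and (xs.min() < lo or xs.max() > hi):
            logger.warning("predict_slice extrapolates beyond the design range")
    else:
        xs = np.asarray(levels if levels is not None
                        else model.categorical[vary_factor])
    rows = []
    for x in xs:
        row = dict(at_values)
        row[vary_factor] = x
        rows.append(row)
    frame = pd.DataFrame(rows)
    X = _design_matrix(frame, model.terms, model.categorical)
    pred = model.results.get_prediction(X)
    ci = pred.conf_int(alpha=0.05)
    return pd.DataFrame({
        vary_factor: xs,
        "predicted": np.asarray(pred.predicted_mean),
        "ci_low": ci[:, 0],
        "ci_high": ci[:, 1],
    })
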