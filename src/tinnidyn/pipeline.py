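"""End-to-end analysis: eligibility -> features -> scaling -> correlation
screen -> penalized ordinal fit -> relevance decomposition -> compliance
sensitivity sweep -> report bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import diary as _diary
from . import features as _features
from . import ordinal as _ordinal
from .diary import CgiOutcome, PatientDiary, compliance, filter_by_compliance
from .features import FEATURE_NAMES, PREDICTOR_NAMES
from .ordinal import NestedCvResult, OrdinalNetFit, nested_cv

logger = logging.getLogger(__name__)

SWEEP_RATES: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.901, 0.05), 2))


def scale_features(F: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Z-score every feature column on the current analysis sample.

    Returns the scaled frame plus the means and sds used (for reporting).
    Raises on missing values or a zero-variance column, naming the feature.
    """
    if F.shape[0] < 2:
        raise ValueError("scaling requires at least 2 patients")
    if F.isna().any().any():
        bad = F.columns[F.isna().any()].tolist()
        raise ValueError(f"feature matrix contains missing values in {bad[:5]}")
    mu = F.mean(axis=0)
    sd = F.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance feature column: {zero.index[0]!r}")
    return (F - mu) / sd, mu, sd


@dataclass
class CorrelationScreen:
    """Spearman correlations of each of the 100 features with CGI-I.

    ``grid`` is a 10x10 frame (rows: time-series features, columns:
    questions) with rows and columns ordered by their mean coefficient.
    No p-values are computed and no multiplicity correction applied: the
    screen is descriptive only.
    """

    rho: pd.Series  # indexed by predictor name
    grid: pd.DataFrame
    flagged: list[str]  # constant columns with undefined correlation


def spearman_screen(
    F: pd.DataFrame, y, order_by: str = "signed"
) -> CorrelationScreen:
    """Rank-based (average-rank ties) correlation of each feature with CGI-I."""
    y = np.asarray(y, dtype=float)
    if len(y) != F.shape[0]:
        raise ValueError("outcome length must match the number of patients")
    rho = {}
    flagged = []
    for col in F.columns:
        x = F[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rho[col] = np.nan
            flagged.append(col)
            continue
        rho[col] = stats.spearmanr(x, y).statistic
    rho = pd.Series(rho, name="rho")

    questions = list(_diary.QUESTION_CODES)
    grid = pd.DataFrame(
        {q: [rho.get(f"{q}_{f}", np.nan) for f in FEATURE_NAMES] for q in questions},
        index=list(FEATURE_NAMES),
    )
    key = grid if order_by == "signed" else grid.abs()
    grid = grid.loc[
        key.mean(axis=1).sort_values(ascending=False).index,
        key.mean(axis=0).sort_values(ascending=False).index,
    ]
    return CorrelationScreen(rho=rho, grid=grid, flagged=flagged)


@dataclass
class RelevanceDecomposition:
    """Marginal |log-odds| sums of a fitted coefficient vector.

    Summing |beta| over features within each question and over questions
    within each feature conserves the total: both margins sum to ||beta||_1.
    """

    per_question: pd.Series
    per_feature: pd.Series


def relevance(fit: OrdinalNetFit) -> RelevanceDecomposition:
    if fit.feature_names is None:
        raise ValueError("fit has no feature names; relevance needs named coefficients")
    beta = pd.Series(np.abs(fit.beta), index=list(fit.feature_names))
    per_q = pd.Series(0.0, index=list(_diary.QUESTION_CODES))
    per_f = pd.Series(0.0, index=list(FEATURE_NAMES))
    for name, b in beta.items():
        q, _, f = name.rpartition("_")
        per_q[q] += b
        per_f[f] += b
    return RelevanceDecomposition(per_question=per_q, per_feature=per_f)


def prepare_design(
    diaries: list[PatientDiary],
    outcomes: list[CgiOutcome],
    min_rate: float = 0.50,
    *,
    precomputed: pd.DataFrame | None = None,
    feature_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Eligibility + compliance filter + feature extraction for one analysis.

    Returns the (unscaled) complete feature matrix, the aligned CGI vector
    and the retained patient ids. Patients failing variability eligibility
    or carrying any NaN feature sentinel are dropped (and logged).
    """
    cgi_by_id = {o.patient_id: o.cgi for o in outcomes}
    kept = [p for p in filter_by_compliance(diaries, min_rate) if p.patient_id in cgi_by_id]
    kept = [p for p in kept if _diary.variability_eligible(p)]
    if precomputed is not None:
        F = precomputed.loc[[p.patient_id for p in kept]]
    else:
        F, _ = _features.feature_matrix(kept, **(feature_kwargs or {}))
    incomplete = F.index[F.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "dropping %d patients with incomplete feature vectors", len(incomplete)
        )
        F = F.drop(index=incomplete)
    y = np.array([cgi_by_id[pid] for pid in F.index])
    return F, y, list(F.index)


@dataclass
class SensitivityCurve:
    """Nested-CV results across minimum-compliance thresholds 0.50..0.90."""

    table: pd.DataFrame  # rate, n, chosen_lambda, test_mcfadden, n_nonzero
    nonzero_sets: dict[float, tuple[str, ...]]
    skipped: list[float]


def sensitivity_sweep(
    diaries: list[PatientDiary],
    outcomes: list[CgiOutcome],
    rates=SWEEP_RATES,
    seed: int = 17,
    min_n: int = 30,
    feature_kwargs: dict | None = None,
) -> SensitivityCurve:
    """Re-run the tuned ordinal fit at each minimum compliance rate.

    Features are extracted once per patient (a patient's series does not
    depend on the threshold); each rate re-selects the subsample, rescales
    inside CV folds, and re-tunes lambda with the same seed policy.
    Subsamples below ``min_n`` patients are skipped with a warning.
    """
    F_all, _ = _features.feature_matrix(
        [p for p in diaries if _is_eligible(p)], **(feature_kwargs or {})
    )
    rows = []
    nonzero_sets: dict[float, tuple[str, ...]] = {}
    skipped: list[float] = []
    for rate in rates:
        F, y, _ids = prepare_design(
            diaries, outcomes, float(rate), precomputed=F_all
        )
        if F.shape[0] < min_n:
            logger.warning(
                "rate %.2f retains only %d patients (<%d); skipped", rate, F.shape[0], min_n
            )
            skipped.append(float(rate))
            continue
        res = nested_cv(
            F.to_numpy(), y, seed=seed, feature_names=tuple(F.columns)
        )
        nz = tuple(
            n for n, b in zip(F.columns, res.final_fit.beta) if b != 0
        )
        nonzero_sets[float(rate)] = nz
        rows.append(
            {
                "rate": float(rate),
                "n": F.shape[0],
                "chosen_lambda": res.chosen_lambda,
                "test_mcfadden": res.test_mcfadden,
                "n_nonzero": res.final_fit.n_nonzero,
            }
        )
    return SensitivityCurve(
        table=pd.DataFrame(rows), nonzero_sets=nonzero_sets, skipped=skipped
    )


def _is_eligible(p: PatientDiary) -> bool:
    try:
        return _diary.variability_eligible(p)
    except _diary.DiaryValidationError:
        return False


def cgi_distribution(outcomes: list[CgiOutcome]) -> pd.DataFrame:
    """Counts and integer-rounded percentages per CGI-I category 1..7.

    Rounded percentages need not sum to exactly 100.
    """
    counts = pd.Series(0, index=range(1, 8), dtype=int)
    for o in outcomes:
        counts[o.cgi] += 1
    pct = 100.0 * counts / max(counts.sum(), 1)
    return pd.DataFrame(
        {"count": counts, "pct": pct, "pct_rounded": pct.round(0).astype(int)}
    )


def run_report(config: dict) -> dict:
    """Run the whole analysis from a config dict and write a report bundle.

    Config keys: ``diary`` and ``outcomes`` (CSV paths) or ``simulate``
    (SyntheticConfig kwargs), ``outdir``, ``seed``, ``min_rate`` (default
    0.50), ``sweep`` (bool), optional ``metadata`` CSV path and ``trend``
    {span, degree}. All numeric products are CSV/JSON; reruns with the
    same config and seed are byte-identical.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 17))
    min_rate = float(config.get("min_rate", 0.50))
    trend_cfg = config.get("trend", {})
    feature_kwargs = {
        k: trend_cfg[k] for k in ("span", "degree") if k in trend_cfg
    }

    if "simulate" in config:
        from .simulate import SyntheticConfig, generate

        sim = SyntheticConfig(**{**config["simulate"], "seed": seed})
        diaries, outcomes, _truth = generate(sim)
    else:
        diaries = _diary.read_diary(config["diary"])
        outcomes = _diary.read_outcomes(config["outcomes"])

    F, y, ids = prepare_design(
        diaries, outcomes, min_rate, feature_kwargs=feature_kwargs
    )
    Fs, mu, sd = scale_features(F)

    # descriptive products
    kept_set = set(ids)
    comp = pd.Series(
        {p.patient_id: compliance(p) for p in diaries if p.patient_id in kept_set}
    )
    descr = {
        "n_patients": len(ids),
        "mean_compliance_pct": round(float(100 * comp.mean()), 1),
        "sd_compliance_pct": round(float(100 * comp.std(ddof=1)), 1),
    }
    meta_path = config.get("metadata")
    if meta_path:
        meta = pd.read_csv(meta_path, dtype={"patient_id": str}).set_index("patient_id")
        meta = meta.loc[meta.index.intersection(ids)]
        for col in ("age", "thi", "phq9"):
            if col in meta.columns:
                descr[f"mean_{col}"] = round(float(meta[col].mean()), 1)
                descr[f"sd_{col}"] = round(float(meta[col].std(ddof=1)), 1)
        if "sex" in meta.columns:
            descr["pct_female"] = round(
                float(100 * (meta["sex"].astype(str).str.lower() == "f").mean()), 1
            )

    dist = cgi_distribution([o for o in outcomes if o.patient_id in kept_set])
    screen = spearman_screen(F, y)
    res = nested_cv(
        F.to_numpy(), y, seed=seed, feature_names=tuple(F.columns)
    )
    rel = relevance(res.final_fit)

    coefs = pd.Series(res.final_fit.beta, index=list(F.columns), name="log_odds")
    nonzero = coefs[coefs != 0]

    dist.to_csv(outdir / "cgi_distribution.csv", index_label="cgi")
    screen.grid.to_csv(outdir / "correlation_grid.csv")
    screen.rho.to_csv(outdir / "correlations.csv", index_label="feature")
    coefs.to_csv(outdir / "coefficients.csv", index_label="feature")
    rel.per_question.to_csv(outdir / "relevance_questions.csv", index_label="question")
    rel.per_feature.to_csv(outdir / "relevance_features.csv", index_label="feature")

    summary = {
        "descriptives": descr,
        "cgi_pct_rounded": {int(k): int(v) for k, v in dist["pct_rounded"].items()},
        "cgi_pct_rounded_sum": int(dist["pct_rounded"].sum()),
        "rounding_note": "rounded category percentages need not sum to exactly 100",
        "chosen_lambda": res.chosen_lambda,
        "test_mcfadden": res.test_mcfadden,
        "per_fold_mcfadden": res.per_fold_mcfadden,
        "n_nonzero": res.final_fit.n_nonzero,
        "nonzero_coefficients": {k: round(float(v), 3) for k, v in nonzero.items()},
    }

    if config.get("sweep"):
        curve = sensitivity_sweep(
            diaries, outcomes, seed=seed, feature_kwargs=feature_kwargs
        )
        curve.table.to_csv(outdir / "sensitivity_curve.csv", index=False)
        summary["sensitivity"] = curve.table.to_dict(orient="records")
        summary["sensitivity_nonzero"] = {
            f"{r:.2f}": list(v) for r, v in curve.nonzero_sets.items()
        }

    cfg_ser = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config_hash": hashlib.sha256(cfg_ser.encode()).hexdigest(),
        "seed": seed,
        "min_rate": min_rate,
        "n_patients": len(ids),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return summary
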