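"""Harmonization benchmarks: effect sizes, rank tests, matching, bootstrap.

Harmonization succeeds when, on a demographically matched two-site cohort,
(i) medium-to-large between-site effects (|Cohen's d| > 0.5) shrink to
small ones (|d| < 0.2) and (ii) significant Mann-Whitney median differences
(p < 0.05) become non-significant — while age and sex remain predictable
from the latent space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import maximum_bipartite_matching
from scipy.stats import norm, rankdata

from connharm.io import Cohort, SubjectRecord
from connharm.measures import MEASURE_NAMES
from connharm.vae import ModelConfig, TrainedModel, encode, predict_heads, train


@dataclass(frozen=True)
class EffectSizeReport:
    """Between-site effect size and rank test for one measure/phase."""

    measure_name: str
    cohens_d: float
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    significant: bool


@dataclass(frozen=True)
class MatchedPairSet:
    """A 1:1 cross-site demographic matching."""

    pairs: tuple[tuple[SubjectRecord, SubjectRecord], ...]
    unmatched: tuple[SubjectRecord, ...]


@dataclass(frozen=True)
class BiologyReport:
    """How well the latent space retains biological covariates."""

    sex_accuracy: float
    age_mae: float  # years
    age_r2: float


def cohens_d(sample1: Sequence[float], sample2: Sequence[float]) -> float:
    """Pooled-SD standardized mean difference ``(m1 - m2) / s_pooled``.

    ``s_pooled = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2))`` with
    unbiased sample variances. NaN when the pooled variance is zero.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("cohens_d needs at least 2 observations per sample")
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def mann_whitney_u(
    sample1: Sequence[float], sample2: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (midranks; normal approximation).

    Returns ``(U1, p)`` where ``U1`` is the statistic of the first sample.
    The p-value uses the tie-corrected normal approximation with a 0.5
    continuity correction. When every value is identical across both
    samples the U variance is undefined and p = 1.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("mann_whitney_u needs non-empty samples")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return float(u1), 1.0
    mu_u = n1 * n2 / 2.0
    diff = u1 - mu_u
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var_u)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return float(u1), float(p)


# ---------------------------------------------------------------------------
# demographic matching
# ---------------------------------------------------------------------------


def match_cohorts(
    site_a: Iterable[SubjectRecord],
    site_b: Iterable[SubjectRecord],
    age_tolerance: float = 1.0,
) -> MatchedPairSet:
    """Maximum-cardinality 1:1 cross-site matching on demographics.

    A pair is admissible when both records have the same sex and their ages
    differ by at most ``age_tolerance`` years. Solved as maximum bipartite
    matching (not greedily), deterministic given input order.
    """
    a = tuple(site_a)
    b = tuple(site_b)
    if not a or not b:
        return MatchedPairSet(pairs=(), unmatched=tuple(a) + tuple(b))
    adm = np.zeros((len(a), len(b)), dtype=np.int8)
    for i, ra in enumerate(a):
        for j, rb in enumerate(b):
            if ra.sex == rb.sex and abs(ra.age - rb.age) <= age_tolerance:
                adm[i, j] = 1
    match = maximum_bipartite_matching(csr_array(adm), perm_type="column")
    pairs = []
    used_b = set()
    for i, j in enumerate(match):
        if j >= 0:
            pairs.append((a[i], b[j]))
            used_b.add(j)
    unmatched = tuple(r for i, r in enumerate(a) if match[i] < 0) + tuple(
        r for j, r in enumerate(b) if j not in used_b
    )
    return MatchedPairSet(pairs=tuple(pairs), unmatched=unmatched)


# ---------------------------------------------------------------------------
# harmonization report
# ---------------------------------------------------------------------------


def effect_size_report(
    table: pd.DataFrame,
    measure: str,
    site_labels: tuple[str, str],
    alpha: float = 0.05,
) -> EffectSizeReport | None:
    """Between-site effect size for one measure column of a tidy table.

    Returns None when either site has fewer than 2 defined values.
    """
    s1 = table.loc[table["site"] == site_labels[0], measure].to_numpy(dtype=float)
    s2 = table.loc[table["site"] == site_labels[1], measure].to_numpy(dtype=float)
    s1, s2 = s1[np.isfinite(s1)], s2[np.isfinite(s2)]
    if s1.size < 2 or s2.size < 2:
        return None
    d = cohens_d(s1, s2)
    u, p = mann_whitney_u(s1, s2)
    return EffectSizeReport(
        measure_name=measure,
        cohens_d=d,
        u_statistic=u,
        p_value=p,
        n1=int(s1.size),
        n2=int(s2.size),
        significant=bool(p < alpha),
    )


def harmonization_report(
    measures_before: pd.DataFrame,
    measures_after: pd.DataFrame,
    site_labels: tuple[str, str],
    alpha: float = 0.05,
    small_effect: float = 0.2,
) -> pd.DataFrame:
    """Before/after between-site comparison for all 12 measures.

    Expects tidy tables with ``site`` plus the 12 measure columns (the
    ``after`` table may carry extra rows for several routes — filter first
    if so). A measure's harmonization is flagged successful when the
    post-harmonization |Cohen's d| is below ``small_effect`` and, if the
    measure was significantly different before, it no longer is after.
    Measures undefined on either side of a phase are skipped.
    """
    rows = []
    for measure in MEASURE_NAMES:
        before = effect_size_report(measures_before, measure, site_labels, alpha)
        after = effect_size_report(measures_after, measure, site_labels, alpha)
        for phase, rep in (("before", before), ("after", after)):
            if rep is None:
                continue
            success = None
            if phase == "after" and before is not None:
                success = bool(
                    abs(rep.cohens_d) < small_effect
                    and (not before.significant or not rep.significant)
                )
            rows.append(
                {
                    "measure": measure,
                    "phase": phase,
                    "cohens_d": rep.cohens_d,
                    "U": rep.u_statistic,
                    "p": rep.p_value,
                    "n1": rep.n1,
                    "n2": rep.n2,
                    "significant": rep.significant,
                    "success_flag": success,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "measure", "phase", "cohens_d", "U", "p", "n1", "n2",
            "significant", "success_flag",
        ],
    )


# ---------------------------------------------------------------------------
# biological preservation
# ---------------------------------------------------------------------------


def biology_report(model: TrainedModel, test_cohort: Cohort) -> BiologyReport:
    """Evaluate the age/sex heads on held-out records.

    Sex accuracy at a 0.5 probability cutoff; age MAE and R^2 in years
    after de-standardization. Uses the deterministic latent mean.
    """
    from connharm.io import vectorize  # local import to avoid cycle at module load

    x = np.stack([model.standardizer.encode_x(vectorize(r.connectome)) for r in test_cohort])
    code = encode(x, model.params)
    site0 = model.site_code(model.site_vocabulary[0])
    age_hat_std, sex_logit, _ = predict_heads(code.mu, site0, model.params)
    age_hat = model.standardizer.decode_age(age_hat_std)
    age_true = np.array([r.age for r in test_cohort], dtype=float)
    sex_true = np.array([r.sex_code for r in test_cohort], dtype=float)
    sex_pred = (sex_logit > 0).astype(float)
    ss_res = float(np.sum((age_true - age_hat) ** 2))
    ss_tot = float(np.sum((age_true - age_true.mean()) ** 2))
    return BiologyReport(
        sex_accuracy=float(np.mean(sex_pred == sex_true)),
        age_mae=float(np.mean(np.abs(age_true - age_hat))),
        age_r2=float(1.0 - ss_res / ss_tot) if ss_tot > 0 else float("nan"),
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_experiments(
    cohort: Cohort,
    measures: pd.DataFrame,
    config: ModelConfig,
    test_cohort: Cohort,
    test_measures_before: pd.DataFrame,
    target_site: str,
    n_iter: int = 100,
    frac: float = 0.8,
    route: str = "recomputed",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Training-stability bootstrap: retrain on random 80% subsamples.

    Each iteration draws ``floor(frac * N)`` training records without
    replacement (seeded ``config.seed + iteration``), retrains, projects
    the *fixed* test cohort to ``target_site`` and records the
    post-harmonization effect sizes (chosen measure ``route``) plus the
    biology report. Returns (per-iteration table, mean +/- SD summary).
    """
    from connharm.harmonize import project_cohort  # avoid circular import

    if not (0 < frac < 1):
        raise ValueError(f"frac must be in (0, 1), got {frac}")
    n_sub = int(frac * len(cohort))
    if n_sub < 2 * config.batch_size:
        raise ValueError(
            f"subsample size {n_sub} < 2 x batch size {config.batch_size}; "
            "reduce batch_size or enlarge the cohort"
        )
    all_ids = [r.subject_id for r in cohort]
    rows = []
    for it in range(n_iter):
        seed = config.seed + it
        rng = np.random.default_rng(seed)
        ids = [all_ids[i] for i in rng.choice(len(all_ids), size=n_sub, replace=False)]
        sub = cohort.subset(ids)
        model = train(sub, measures, replace(config, seed=seed))
        _, after = project_cohort(test_cohort, model, target_site)
        report = harmonization_report(
            test_measures_before,
            after[after["route"] == route],
            site_labels=(model.site_vocabulary[0], model.site_vocabulary[1]),
        )
        bio = biology_report(model, test_cohort)
        post = report[report["phase"] == "after"]
        for rec in post.itertuples(index=False):
            rows.append(
                {
                    "iteration": it,
                    "measure": rec.measure,
                    "abs_cohens_d": abs(rec.cohens_d),
                    "p": rec.p,
                    "sex_accuracy": bio.sex_accuracy,
                    "age_mae": bio.age_mae,
                    "age_r2": bio.age_r2,
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("measure", sort=False)
        .agg(
            abs_cohens_d_mean=("abs_cohens_d", "mean"),
            abs_cohens_d_sd=("abs_cohens_d", "std"),
            p_mean=("p", "mean"),
            sex_accuracy_mean=("sex_accuracy", "mean"),
            sex_accuracy_sd=("sex_accuracy", "std"),
            age_mae_mean=("age_mae", "mean"),
            age_mae_sd=("age_mae", "std"),
        )
        .reset_index()
    )
    return table, summary
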