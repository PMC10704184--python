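"""Statistical evaluation of sequestration balance.

The balance metric for a demographic subcategory with ``N_T`` patients in the
input batch and ``N_Open`` of them in the open arm is the *scaled difference
from expectation*

    d = |f * N_T - N_Open| / (f * N_T),

the relative deviation of the realized open-arm count from its expectation
under an exact ``f`` : ``1-f`` split.  Splitting the same input many times with
independent seeds yields a distribution of ``d`` per subcategory; the
stratified sampler is compared against the naive (unstratified) sampler with a
one-tailed Mann-Whitney U test (alternative: stratified ``d`` is
stochastically smaller), with Holm-Bonferroni correction across the testable
subcategories.  Subcategories with zero input count are untestable and
reported N/A.

For modality subcategories, counts are *possession* counts (a patient can hold
several modalities), so modality prevalences may sum to more than 100%.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .engine import resolve_primary_modality
from .records import PatientRecord, ValidationError, normalize_record
from .scheme import CategoryScheme

Sampler = Literal["stratified", "naive"]
Arm = Literal["open", "sequestered"]

_SAMPLER_CODES = {"stratified": 1, "naive": 2}


class DegenerateCategoryError(ValueError):
    """Raised when a statistic is undefined (e.g. zero input count)."""


class DegeneracyWarning(UserWarning):
    """Emitted when a comparison carries no information (all values tied)."""


def scaled_difference(f: float, n_total: int, n_open: int) -> float:
    """Relative deviation of an open-arm count from its expectation f*N_T.

    Raises :class:`DegenerateCategoryError` for ``n_total == 0`` — callers
    should mark such subcategories N/A rather than score them.
    """
    if not (0.0 < f < 1.0):
        raise ValueError(f"f must be in (0, 1), got {f}")
    if n_total < 1:
        raise DegenerateCategoryError(
            "scaled difference is undefined for an empty subcategory (N_T = 0)"
        )
    if not (0 <= n_open <= n_total):
        raise ValueError(f"n_open must be in [0, {n_total}], got {n_open}")
    expected = f * n_total
    return abs(expected - n_open) / expected


# -- trial ensembles ----------------------------------------------------------


@dataclass(frozen=True)
class TrialEnsemble:
    """Per-trial open-arm counts for every subcategory, over many re-splits.

    ``subcategories`` is an ordered tuple of ``(variable, category)`` pairs;
    ``open_counts`` has shape ``(n_trials, n_subcategories)``.  Sequestered
    counts are implied: open + sequestered = input count, per trial.
    """

    sampler: str
    n_trials: int
    open_fraction: float
    n_patients: int
    master_seed: int
    subcategories: tuple[tuple[str, str], ...]
    input_counts: np.ndarray
    open_counts: np.ndarray
    open_totals: np.ndarray

    @property
    def sequestered_counts(self) -> np.ndarray:
        return self.input_counts[None, :] - self.open_counts

    @property
    def sequestered_totals(self) -> np.ndarray:
        return self.n_patients - self.open_totals

    def column(self, variable: str, category: str) -> int:
        return self.subcategories.index((variable, category))


def _prepare_batch(
    batch: Sequence[PatientRecord], scheme: CategoryScheme
) -> tuple[np.ndarray, tuple[tuple[str, str], ...], np.ndarray]:
    """Subcategory indicator matrix, column index, and stratum id per patient.

    Demographic columns are one-hot on the normalized category; modality
    columns mark possession of each modality code.
    """
    primaries = resolve_primary_modality(batch)
    keys = [normalize_record(p, scheme, primaries[p.patient_id]) for p in batch]
    subcats: list[tuple[str, str]] = [
        (var, c) for var, cats in scheme.variables for c in cats
    ]
    col = {sc: j for j, sc in enumerate(subcats)}
    n = len(batch)
    M = np.zeros((n, len(subcats)), dtype=np.int64)
    for i, (p, key) in enumerate(zip(batch, keys)):
        for var, val in zip(key.variables, key.values):
            if var != "modality":
                M[i, col[(var, val)]] = 1
        for m in p.modalities:
            j = col.get(("modality", m))
            if j is not None:
                M[i, j] = 1
    key_index = {k: i for i, k in enumerate(sorted(set(keys), key=lambda k: k.content()))}
    sid = np.array([key_index[k] for k in keys], dtype=np.int64)
    return M, tuple(subcats), sid


def run_trials(
    batch: Sequence[PatientRecord],
    scheme: CategoryScheme,
    sampler: Sampler,
    n_trials: int,
    master_seed: int,
    open_fraction: float | None = None,
) -> TrialEnsemble:
    """Split the same input batch ``n_trials`` times with independent seeds.

    Each trial is an independent split of the full batch (no registry
    carry-over) using the per-stratum counting rule of the engine: a stratum of
    size m sends floor(f*m) + Bernoulli(frac(f*m)) members to the open arm,
    selected uniformly.  Trial t draws from a stream keyed by
    (master_seed, sampler, t), so ensembles are reproducible and the two
    samplers' streams are independent.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if sampler not in _SAMPLER_CODES:
        raise ValueError(f"unknown sampler {sampler!r}")
    f = scheme.open_fraction if open_fraction is None else open_fraction
    M, subcats, sid = _prepare_batch(batch, scheme)
    n = len(batch)
    if sampler == "naive":
        sid = np.zeros(n, dtype=np.int64)

    order0 = np.argsort(sid, kind="stable")
    sid_sorted = sid[order0]
    M_sorted = M[order0]
    sizes = np.bincount(sid_sorted)
    starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    base_k = np.floor(f * sizes).astype(np.int64)
    frac_k = f * sizes - base_k
    within_offset = np.arange(n) - np.repeat(starts, sizes)

    open_counts = np.zeros((n_trials, len(subcats)), dtype=np.int64)
    open_totals = np.zeros(n_trials, dtype=np.int64)
    code = _SAMPLER_CODES[sampler]
    for t in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), code, t]))
        u = rng.random(n)
        k = base_k + (rng.random(len(sizes)) < frac_k)
        ranks = np.lexsort((u, sid_sorted))
        open_in_rank_order = within_offset < np.repeat(k, sizes)
        mask = np.empty(n, dtype=bool)
        mask[ranks] = open_in_rank_order
        open_counts[t] = mask @ M_sorted
        open_totals[t] = int(k.sum())

    return TrialEnsemble(
        sampler=sampler,
        n_trials=n_trials,
        open_fraction=f,
        n_patients=n,
        master_seed=int(master_seed),
        subcategories=subcats,
        input_counts=M.sum(axis=0),
        open_counts=open_counts,
        open_totals=open_totals,
    )


def scaled_differences(ensemble: TrialEnsemble, arm: Arm = "open") -> np.ndarray:
    """Per-trial scaled differences, shape (n_trials, n_subcategories).

    Columns with zero input count are NaN (untestable).  For the sequestered
    arm the expectation uses ``1 - f`` and the sequestered counts.
    """
    if arm == "open":
        f = ensemble.open_fraction
        counts = ensemble.open_counts
    else:
        f = 1.0 - ensemble.open_fraction
        counts = ensemble.sequestered_counts
    expected = f * ensemble.input_counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.abs(expected[None, :] - counts) / expected[None, :]
    d[:, ensemble.input_counts == 0] = np.nan
    return d


def prevalence_summary(ensemble: TrialEnsemble) -> pd.DataFrame:
    """Mean (SD) prevalence per subcategory in both arms, across trials.

    Prevalence within a trial is the subcategory's patient count in the arm
    divided by the arm's total patient count, in percent.  SD is the sample
    standard deviation across trials (0 for a single trial).
    """
    open_prev = 100.0 * ensemble.open_counts / ensemble.open_totals[:, None]
    seq_prev = 100.0 * ensemble.sequestered_counts / ensemble.sequestered_totals[:, None]
    ddof = 1 if ensemble.n_trials > 1 else 0
    df = pd.DataFrame(
        {
            "variable": [v for v, _ in ensemble.subcategories],
            "subcategory": [c for _, c in ensemble.subcategories],
            "input_count": ensemble.input_counts,
            "input_prevalence_pct": 100.0 * ensemble.input_counts / ensemble.n_patients,
            "open_mean_pct": open_prev.mean(axis=0),
            "open_sd_pct": open_prev.std(axis=0, ddof=ddof),
            "sequestered_mean_pct": seq_prev.mean(axis=0),
            "sequestered_sd_pct": seq_prev.std(axis=0, ddof=ddof),
        }
    )
    return df


# -- hypothesis testing -------------------------------------------------------


def _exact_mannwhitney_less(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Enumerate the permutation distribution of U (midranks, ties allowed)."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    count = 0
    total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(comb)].sum() - offset
        count += u <= u_obs + 1e-9
        total += 1
    return float(u_obs), count / total


def mann_whitney_one_tailed(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = 10
) -> tuple[float, float]:
    """One-tailed Mann-Whitney U: alternative "x stochastically less than y".

    Returns ``(U, p)`` where U is the statistic for ``x``.  Ties take
    midranks.  When both samples have at most ``exact_threshold`` values the
    p-value is computed by full enumeration of the permutation distribution;
    otherwise the normal approximation with tie-corrected variance and
    continuity correction is used.  If every value in both samples is
    identical the comparison is uninformative: p = 1 with a
    :class:`DegeneracyWarning`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn(
            "all values identical in both samples; Mann-Whitney U is uninformative",
            DegeneracyWarning,
            stacklevel=2,
        )
        return float(x.size * y.size / 2.0), 1.0
    if x.size <= exact_threshold and y.size <= exact_threshold:
        return _exact_mannwhitney_less(x, y)
    res = stats.mannwhitneyu(x, y, alternative="less", use_continuity=True,
                             method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Holm step-down significance flags, in input order.

    The i-th smallest of m p-values is tested against alpha/(m - i + 1)
    (equivalently: each p-value against alpha divided by its rank when the
    smallest p carries rank m); the step-down stops at the first failure.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject


@dataclass(frozen=True)
class ComparisonReport:
    """Per-subcategory Mann-Whitney comparison of the two samplers.

    ``table`` columns: variable, subcategory, input_count, testable,
    u_statistic, p_value (NaN when untestable), significant_raw,
    significant_holm.  Zero-count subcategories are never given a p-value.
    """

    table: pd.DataFrame
    alpha: float
    n_trials: int
    master_seed: int
    arm: str

    @property
    def n_comparisons(self) -> int:
        return int(self.table["testable"].sum())


def compare_samplers(
    batch: Sequence[PatientRecord],
    scheme: CategoryScheme,
    n_trials: int,
    master_seed: int,
    alpha: float = 0.05,
    open_fraction: float | None = None,
    arm: Arm = "open",
) -> ComparisonReport:
    """Test, per subcategory, whether stratified splitting balances better.

    Runs both samplers ``n_trials`` times on the same batch, computes the
    scaled-difference samples on the chosen arm, and applies the one-tailed
    Mann-Whitney U test (stratified less than naive) with Holm-Bonferroni
    correction across all testable (nonzero-count) subcategories.
    """
    ens_strat = run_trials(batch, scheme, "stratified", n_trials, master_seed,
                           open_fraction)
    ens_naive = run_trials(batch, scheme, "naive", n_trials, master_seed,
                           open_fraction)
    return compare_ensembles(ens_strat, ens_naive, alpha=alpha, arm=arm)


def compare_ensembles(
    ens_strat: TrialEnsemble,
    ens_naive: TrialEnsemble,
    alpha: float = 0.05,
    arm: Arm = "open",
) -> ComparisonReport:
    """Mann-Whitney + Holm comparison of two pre-computed ensembles."""
    if ens_strat.subcategories != ens_naive.subcategories:
        raise ValidationError("ensembles were not computed on the same scheme")
    if not np.array_equal(ens_strat.input_counts, ens_naive.input_counts):
        raise ValidationError("ensembles were not computed on the same input batch")
    d_strat = scaled_differences(ens_strat, arm)
    d_naive = scaled_differences(ens_naive, arm)
    rows = []
    for j, (var, cat) in enumerate(ens_strat.subcategories):
        n_t = int(ens_strat.input_counts[j])
        if n_t == 0:
            rows.append((var, cat, n_t, False, np.nan, np.nan))
            continue
        u, p = mann_whitney_one_tailed(d_strat[:, j], d_naive[:, j])
        rows.append((var, cat, n_t, True, u, p))
    df = pd.DataFrame(
        rows,
        columns=["variable", "subcategory", "input_count", "testable",
                 "u_statistic", "p_value"],
    )
    testable = df["testable"].to_numpy()
    flags = np.zeros(len(df), dtype=bool)
    if testable.any():
        flags[testable] = holm_bonferroni(df.loc[testable, "p_value"], alpha=alpha)
    df["significant_raw"] = testable & (df["p_value"].to_numpy() < alpha)
    df["significant_holm"] = flags
    return ComparisonReport(
        table=df,
        alpha=alpha,
        n_trials=ens_strat.n_trials,
        master_seed=ens_strat.master_seed,
        arm=arm,
    )
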