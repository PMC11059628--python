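"""Per-molecule and per-site methylation statistics.

Two statistical layers coexist in single-molecule methylation analysis:

* **molecule level** -- the methylation proportion per molecule (mPPM): for
  one read and one context, the fraction of that context's sites called
  methylated.  Differences between conditions in the *distribution* of mPPM
  (DmPPM) are tested with the Kruskal-Wallis rank test on molecules pooled
  across replicates, because epiallele shifts move whole subpopulations of
  molecules rather than the mean of every site.

* **site / region level** -- per-site mean methylation across molecules
  (non-missing denominator) and, for testing, one regional mean per biological
  replicate, compared across conditions with one-way ANOVA plus post-hoc Tukey
  HSD (studentized range).

The module also provides replicate/external-table correlations of per-site
levels, within-molecule cross-context statistics (CG vs CHG vs CHH mPPM
ordering and coupling), and the logarithmic regression of pooled read counts
on target GC content used for capture-bias QC.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calls import MISSING, MoleculeCall
from .targets import CONTEXTS, CytosineSite

log = logging.getLogger(__name__)


@dataclass
class MPPMRecord:
    """Methylation proportion per molecule for one read and one context."""

    read_id: str
    target_id: str
    sample: str
    replicate: str
    context: str
    n_sites: int
    n_meth: int

    @property
    def mppm(self) -> float:
        return self.n_meth / self.n_sites


@dataclass
class DmPPMResult:
    """Two-group Kruskal-Wallis comparison of mPPM distributions."""

    target_id: str
    context: str
    sample_pair: tuple[str, str]
    statistic: float
    p_value: float
    median_diff: float
    significant: bool
    n_a: int = 0
    n_b: int = 0


def mppm(
    call: MoleculeCall, sites: Sequence[CytosineSite], context: str
) -> MPPMRecord | None:
    """mPPM record for one full-length read; None when the target has no
    sites of ``context`` (omitted, not zero)."""
    sub = call.context_calls(sites, context)
    if sub.size == 0:
        return None
    if (sub == MISSING).any():
        raise ValueError(
            f"{call.read_id}: mPPM requires a full-length read "
            f"(missing {context} calls present)"
        )
    return MPPMRecord(
        read_id=call.read_id,
        target_id=call.target_id,
        sample=call.sample,
        replicate=call.replicate,
        context=context,
        n_sites=int(sub.size),
        n_meth=int((sub == 1).sum()),
    )


def mppm_table(
    calls: Sequence[MoleculeCall],
    sites: Sequence[CytosineSite],
    contexts: Sequence[str] = CONTEXTS,
) -> pd.DataFrame:
    """Tidy mPPM table over the filtered, full-length reads of one target."""
    rows = []
    for call in calls:
        if not call.full_length:
            continue
        for context in contexts:
            rec = mppm(call, sites, context)
            if rec is not None:
                rows.append(
                    {
                        "read_id": rec.read_id,
                        "target_id": rec.target_id,
                        "sample": rec.sample,
                        "replicate": rec.replicate,
                        "context": rec.context,
                        "n_sites": rec.n_sites,
                        "n_meth": rec.n_meth,
                        "mppm": rec.mppm,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "target_id",
            "sample",
            "replicate",
            "context",
            "n_sites",
            "n_meth",
            "mppm",
        ],
    )


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value.

    Degenerate input where every observation is identical gives H = 0, p = 1
    (scipy raises in that case).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def dmppm_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    target_id: str = "",
    context: str = "",
    sample_pair: tuple[str, str] = ("A", "B"),
    alpha: float = 0.05,
) -> DmPPMResult:
    """Differential methylation proportion per molecule between two conditions.

    Molecules are pooled across replicates within each condition; the test is
    the two-group Kruskal-Wallis rank test (equivalent to the Wilcoxon
    rank-sum up to the chi-square approximation).  A group with fewer than two
    values yields an NA result with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        log.warning(
            "dmppm_test %s/%s %s: group with < 2 molecules, returning NA",
            target_id,
            context,
            sample_pair,
        )
        return DmPPMResult(
            target_id,
            context,
            sample_pair,
            float("nan"),
            float("nan"),
            float("nan"),
            False,
            a.size,
            b.size,
        )
    h, p = kruskal_wallis(a, b)
    median_diff = float(np.median(b) - np.median(a))
    return DmPPMResult(
        target_id, context, sample_pair, h, p, median_diff, bool(p < alpha), a.size, b.size
    )


def pairwise_dmppm(
    groups: Mapping[str, Sequence[float]],
    target_id: str = "",
    context: str = "",
    alpha: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """All pairwise DmPPM tests across conditions.

    P-values are reported raw; ``adjust="bh"`` adds a Benjamini-Hochberg
    adjusted column (significance stays on the raw p, matching common
    practice of annotating unadjusted pairwise asterisks).
    """
    rows = []
    for (name_a, a), (name_b, b) in itertools.combinations(groups.items(), 2):
        res = dmppm_test(a, b, target_id, context, (name_a, name_b), alpha)
        rows.append(
            {
                "target_id": target_id,
                "context": context,
                "group_a": name_a,
                "group_b": name_b,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "H": res.statistic,
                "p_value": res.p_value,
                "median_diff": res.median_diff,
                "significant": res.significant,
            }
        )
    frame = pd.DataFrame(rows)
    if adjust == "bh" and len(frame):
        from statsmodels.stats.multitest import multipletests

        mask = frame["p_value"].notna()
        adjusted = np.full(len(frame), np.nan)
        if mask.any():
            adjusted[mask.to_numpy()] = multipletests(
                frame.loc[mask, "p_value"], method="fdr_bh"
            )[1]
        frame["p_adj_bh"] = adjusted
    return frame


def site_levels(
    calls: Sequence[MoleculeCall], sites: Sequence[CytosineSite], context: str
) -> np.ndarray:
    """Per-site mean methylation level across molecules for one context.

    Each site's level uses only the molecules with a non-missing call at that
    site; a site covered by no molecule is NaN.
    """
    idx = [s.index for s in sites if s.context == context]
    if not idx:
        return np.array([])
    matrix = np.array([c.calls[idx] for c in calls], dtype=float)
    if matrix.size == 0:
        return np.full(len(idx), np.nan)
    matrix[matrix == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(matrix, axis=0)


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across condition groups.

    Degenerate input with every observation identical (zero between- and
    within-group variance) gives F = 0, p = 1 instead of scipy's NaN.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def tukey_hsd(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons via the studentized range distribution.

    Uses the Tukey-Kramer standard error for (possibly) unequal group sizes:
    ``q = |mean_j - mean_i| / sqrt((MSW / 2) (1/n_i + 1/n_j))`` with p-value
    from the studentized range with k groups and N - k error df.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"g{i}" for i in range(len(arrays))]
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    n_total = int(ns.sum())
    df_error = n_total - k
    if df_error <= 0:
        raise ValueError("Tukey HSD needs residual degrees of freedom > 0")
    means = np.array([a.mean() for a in arrays])
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    msw = ss_within / df_error
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[j] - means[i]
        se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else float("inf")
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_error)) if np.isfinite(q) else 0.0
        p = min(max(p, 0.0), 1.0)
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(diff),
                "q": float(q),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def site_levels_and_anova(
    calls: Sequence[MoleculeCall],
    sites: Sequence[CytosineSite],
    context: str,
    subregion: tuple[int, int] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict, pd.DataFrame | None]:
    """Per-site level profiles plus the regional replicate-level ANOVA/Tukey.

    Profiles pool replicates within each condition (for plotting).  For
    testing, each biological replicate contributes one regional mean -- the
    mean over the subregion's per-site levels computed within that replicate
    -- and the condition groups of replicate means enter one-way ANOVA with
    post-hoc Tukey HSD.  ``subregion`` is a half-open window over the
    context-subsequence site indices (None = whole region).

    Returns ``(profile_frame, anova_dict, tukey_frame)``; the test entries are
    None/NaN when any condition has fewer than two replicates.
    """
    idx = [s.index for s in sites if s.context == context]
    conditions = sorted({c.sample for c in calls})
    profile_rows = []
    for condition in conditions:
        cond_calls = [c for c in calls if c.sample == condition]
        levels = site_levels(cond_calls, sites, context)
        for sub_i, (site_list_i, level) in enumerate(zip(idx, levels)):
            profile_rows.append(
                {
                    "sample": condition,
                    "context": context,
                    "context_index": sub_i,
                    "site_index": site_list_i,
                    "level": float(level),
                }
            )
    profile = pd.DataFrame(
        profile_rows, columns=["sample", "context", "context_index", "site_index", "level"]
    )

    lo, hi = (0, len(idx)) if subregion is None else subregion
    groups: list[list[float]] = []
    group_labels: list[str] = []
    enough_replicates = True
    for condition in conditions:
        replicate_means = []
        replicates = sorted(
            {c.replicate for c in calls if c.sample == condition}
        )
        for replicate in replicates:
            rep_calls = [
                c for c in calls if c.sample == condition and c.replicate == replicate
            ]
            levels = site_levels(rep_calls, sites, context)[lo:hi]
            levels = levels[~np.isnan(levels)]
            if levels.size:
                replicate_means.append(float(levels.mean()))
        if len(replicate_means) < 2:
            enough_replicates = False
        groups.append(replicate_means)
        group_labels.append(condition)

    if len(conditions) < 2 or not enough_replicates:
        log.warning(
            "site_levels_and_anova (%s): < 2 conditions or < 2 replicates in a "
            "condition; ANOVA skipped",
            context,
        )
        return profile, {"F": float("nan"), "p_value": float("nan")}, None

    f, p = anova_oneway(groups)
    tukey = tukey_hsd(groups, group_labels)
    tukey["significant"] = tukey["p_value"] < alpha
    return profile, {"F": f, "p_value": p}, tukey


def level_correlations(
    profile_a: Sequence[float],
    profile_b: Sequence[float],
    method: str = "pearson",
) -> float:
    """Correlation of paired per-site methylation levels over shared sites.

    Sites where either profile is NaN are dropped; fewer than 3 shared sites
    gives NaN.  Used replicate-vs-replicate and assay-vs-external-table, with
    all three contexts pooled.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must be paired over the same sites")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3:
        return float("nan")
    if a.std() == 0 or b.std() == 0:
        return float("nan")  # correlation undefined for a constant profile
    if method == "pearson":
        return float(sps.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(sps.spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def within_molecule_context_stats(
    calls: Sequence[MoleculeCall], sites: Sequence[CytosineSite]
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Cross-context statistics along the same molecules.

    Restricted to full-length reads (covering all sites of all contexts).
    Returns the per-read ``(mppm_CG, mppm_CHG, mppm_CHH)`` triples, the
    fractions of reads with strictly ``mppm_CG > mppm_CHG`` and strictly
    ``mppm_CHG > mppm_CHH``, and the pairwise Pearson correlations between
    context mPPM values across reads.  Statistics involving a context the
    target lacks are NaN.
    """
    table = mppm_table(calls, sites)
    if table.empty:
        empty = pd.DataFrame(columns=["read_id"] + [f"mppm_{c}" for c in CONTEXTS])
        return empty, {"frac_cg_gt_chg": float("nan"), "frac_chg_gt_chh": float("nan")}, (
            pd.DataFrame(np.nan, index=CONTEXTS, columns=CONTEXTS)
        )
    wide = table.pivot_table(index="read_id", columns="context", values="mppm")
    wide = wide.reindex(columns=CONTEXTS)
    wide.columns = [f"mppm_{c}" for c in wide.columns]
    wide = wide.reset_index()

    def _ordering(col_hi: str, col_lo: str) -> float:
        hi = wide[col_hi].to_numpy()
        lo = wide[col_lo].to_numpy()
        ok = ~(np.isnan(hi) | np.isnan(lo))
        if not ok.any():
            return float("nan")
        return float((hi[ok] > lo[ok]).mean())

    fractions = {
        "frac_cg_gt_chg": _ordering("mppm_CG", "mppm_CHG"),
        "frac_chg_gt_chh": _ordering("mppm_CHG", "mppm_CHH"),
    }

    corr = pd.DataFrame(np.nan, index=CONTEXTS, columns=CONTEXTS)
    for ca, cb in itertools.combinations_with_replacement(CONTEXTS, 2):
        a = wide[f"mppm_{ca}"].to_numpy()
        b = wide[f"mppm_{cb}"].to_numpy()
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() >= 3 and np.std(a[ok]) > 0 and np.std(b[ok]) > 0:
            r = float(sps.pearsonr(a[ok], b[ok]).statistic)
            corr.loc[ca, cb] = r
            corr.loc[cb, ca] = r
    return wide, fractions, corr


def load_external_levels(path) -> pd.DataFrame:
    """Load a WGBS-style external per-site methylation table.

    TSV with columns ``chrom, position, context, sample, level``; ``position``
    is the 0-based reference coordinate of the cytosine.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"chrom", "position", "context", "sample", "level"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"external table missing columns: {sorted(missing)}")
    return frame


def external_concordance(
    calls: Sequence[MoleculeCall],
    target,
    external: pd.DataFrame,
    sample: str,
    method: str = "pearson",
) -> float:
    """Correlation of assay per-site levels with an external table.

    Pools all three contexts over the sites shared between the target and the
    external table (matched on reference coordinate); NaN with < 3 shared
    sites.
    """
    from .targets import genomic_position

    sites = target.sites()
    sub = external[
        (external["chrom"] == target.chrom) & (external["sample"] == sample)
    ]
    by_position = dict(zip(sub["position"], sub["level"]))
    ours, theirs = [], []
    for context in CONTEXTS:
        levels = site_levels(calls, sites, context)
        offsets = [s.offset for s in sites if s.context == context]
        for offset, level in zip(offsets, levels):
            position = genomic_position(target, offset)
            if position in by_position and not np.isnan(level):
                ours.append(level)
                theirs.append(by_position[position])
    return level_correlations(ours, theirs, method=method)


def gc_reads_regression(
    gc_content: Sequence[float], read_counts: Sequence[float]
) -> dict:
    """Logarithmic regression of pooled filtered read counts on target GC.

    Fits ``reads = a + b * ln(gc_content)`` by least squares and reports the
    coefficients, R-squared and the slope-test p-value.  Targets with
    non-positive GC are excluded with a warning; at least 3 usable targets are
    required.
    """
    gc = np.asarray(gc_content, dtype=float)
    reads = np.asarray(read_counts, dtype=float)
    if gc.shape != reads.shape:
        raise ValueError("gc_content and read_counts must be paired")
    ok = gc > 0
    if (~ok).any():
        log.warning("gc_reads_regression: %d target(s) with non-positive GC excluded", int((~ok).sum()))
    gc, reads = gc[ok], reads[ok]
    if gc.size < 3:
        raise ValueError("need >= 3 targets with positive GC content")
    if np.all(reads == reads[0]) or np.all(gc == gc[0]):
        return {
            "intercept": float(reads.mean()),
            "slope": 0.0,
            "r_squared": 0.0,
            "p_value": float("nan"),
            "n": int(gc.size),
        }
    fit = sps.linregress(np.log(gc), reads)
    return {
        "intercept": float(fit.intercept),
        "slope": float(fit.slope),
        "r_squared": float(fit.rvalue**2),
        "p_value": float(fit.pvalue),
        "n": int(gc.size),
    }
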