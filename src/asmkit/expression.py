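"""Allelic expression ratios from cDNA amplicon reads.

An exonic heterozygous SNP lets the two alleles' transcripts be counted
separately in cDNA amplicon sequencing (no bisulfite conversion here).  A
shift in the allelic read ratio between untransfected and edited samples
indicates allele-specific silencing; the shift magnitude is summarised as a
ratio fold change and tested with a two-sided equal-variance t-test on
per-replicate allele-1 proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .locus import DiploidLocus, revcomp


def _best_plain_offset(read: str, ref: str) -> Tuple[int, int, str]:
    """Best ungapped (offset, mismatches, oriented read) on a plain
    reference, both orientations."""
    best = None
    for oriented in (read, revcomp(read)):
        m = len(oriented)
        for off in range(len(ref) - m + 1):
            mm = sum(1 for a, b in zip(ref[off : off + m], oriented) if a != b)
            cand = (mm, off, oriented)
            if best is None or cand[0] < best[0]:
                best = cand
    return (best[1], best[0], best[2])


def count_expression_alleles(
    reads: Iterable[str],
    locus: DiploidLocus,
    max_mismatch_frac: float = 0.1,
) -> Tuple[int, int, int]:
    """Count reads per allele at the exonic SNP by exact base matching.

    Returns ``(allele1, allele2, uncounted)``; reads not covering the SNP,
    not matching either allele base exactly (e.g. N), or not aligning are
    uncounted.  Raises when no read is countable.
    """
    ref = locus.sequence
    n1 = n2 = uncounted = 0
    for read in reads:
        read = read.upper()
        if not read or len(read) > len(ref):
            uncounted += 1
            continue
        off, mm, oriented = _best_plain_offset(read, ref)
        # SNP mismatch must not penalise allele-2 reads
        if mm / max(len(read), 1) > max_mismatch_frac + 1.0 / len(read):
            uncounted += 1
            continue
        i = locus.snp_pos - off
        if not 0 <= i < len(oriented):
            uncounted += 1
            continue
        obs = oriented[i]
        if obs == locus.allele1_base:
            n1 += 1
        elif obs == locus.allele2_base:
            n2 += 1
        else:
            uncounted += 1
    if n1 + n2 == 0:
        raise ValueError("no countable reads at the exonic SNP")
    return n1, n2, uncounted


def ratio_fold_change(
    pre_counts: Tuple[int, int],
    post_counts: Tuple[int, int],
) -> Tuple[float, int]:
    """Fold change of the allelic expression ratio between two samples.

    ``fold = max(r_post/r_pre, r_pre/r_post)`` with ``r = allele1/allele2``;
    the direction is the sign of ``log(r_post/r_pre)``.  All four counts must
    be positive.
    """
    a1, a2 = pre_counts
    b1, b2 = post_counts
    if min(a1, a2, b1, b2) <= 0:
        raise ValueError("all pooled allele counts must be positive")
    r_pre = a1 / a2
    r_post = b1 / b2
    fold = max(r_post / r_pre, r_pre / r_post)
    direction = int(np.sign(np.log(r_post / r_pre)))
    return fold, direction


@dataclass
class ShiftTest:
    t: float
    p: float
    zero_variance: bool = False


def allele_shift_test(
    pre_proportions: Sequence[float],
    post_proportions: Sequence[float],
    log_ratio: bool = False,
) -> ShiftTest:
    """Two-sample two-sided t-test (pooled variance) on per-replicate
    allele-1 proportions (or log allele ratios with ``log_ratio``).

    Zero pooled variance is flagged rather than returned as NaN: equal means
    give (t=0, p=1), unequal means (t=inf sign, p=0) with the flag set.
    """
    x = np.asarray(pre_proportions, dtype=float)
    y = np.asarray(post_proportions, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >=2 replicates per condition")
    if log_ratio:
        x = np.log(x / (1 - x))
        y = np.log(y / (1 - y))
    sp2 = (np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)) / (len(x) + len(y) - 2)
    if sp2 == 0:
        if np.isclose(x.mean(), y.mean()):
            return ShiftTest(t=0.0, p=1.0, zero_variance=True)
        return ShiftTest(
            t=float(np.sign(x.mean() - y.mean()) * np.inf), p=0.0, zero_variance=True
        )
    import warnings

    with warnings.catch_warnings():
        # near-degenerate variance is legitimate here (deep replicates)
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(x, y, equal_var=True)
    return ShiftTest(t=float(t), p=float(p))


@dataclass
class AlleleExpression:
    """Full allelic-expression comparison for one locus."""

    locus_name: str
    pre_counts: pd.DataFrame  # columns replicate, allele1, allele2
    post_counts: pd.DataFrame
    fold: float = float("nan")
    direction: int = 0
    test: Optional[ShiftTest] = None

    @staticmethod
    def _props(df: pd.DataFrame) -> np.ndarray:
        tot = df["allele1"] + df["allele2"]
        return (df["allele1"] / tot).to_numpy(dtype=float)

    @property
    def pre_proportions(self) -> np.ndarray:
        return self._props(self.pre_counts)

    @property
    def post_proportions(self) -> np.ndarray:
        return self._props(self.post_counts)

    def as_row(self) -> dict:
        pre = self.pre_counts[["allele1", "allele2"]].sum()
        post = self.post_counts[["allele1", "allele2"]].sum()
        return {
            "locus": self.locus_name,
            "pre_allele1": int(pre["allele1"]),
            "pre_allele2": int(pre["allele2"]),
            "post_allele1": int(post["allele1"]),
            "post_allele2": int(post["allele2"]),
            "pre_ratio": pre["allele1"] / pre["allele2"],
            "post_ratio": post["allele1"] / post["allele2"],
            "fold_change": self.fold,
            "direction": self.direction,
            "t": self.test.t if self.test else None,
            "p": self.test.p if self.test else None,
        }


def analyze_expression(
    pre_counts: pd.DataFrame,
    post_counts: pd.DataFrame,
    locus_name: str = "",
    log_ratio: bool = False,
) -> AlleleExpression:
    """Fold change (on pooled counts) plus the replicate-level shift test."""
    result = AlleleExpression(locus_name=locus_name, pre_counts=pre_counts, post_counts=post_counts)
    pre = pre_counts[["allele1", "allele2"]].sum()
    post = post_counts[["allele1", "allele2"]].sum()
    result.fold, result.direction = ratio_fold_change(
        (int(pre["allele1"]), int(pre["allele2"])),
        (int(post["allele1"]), int(post["allele2"])),
    )
    result.test = allele_shift_test(
        result.pre_proportions, result.post_proportions, log_ratio=log_ratio
    )
    return result
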