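"""ASM summary statistics: CpG selection, Δ%, ratio, footprint, stability.

The headline statistics of an allele-specific methylation (ASM) experiment
are computed over a fixed CpG selection: all CpGs whose level on the
guide-treated on-target allele reaches at least half the maximum level
delivered there.  The same CpG set is reused for every sample and allele of
the locus.  ASM Δ% is the difference, and the ASM ratio the quotient, of the
methylation *gains* (treated minus untransfected) at the on- and off-target
alleles, averaged over the selected CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .quant import MethylationProfile

QUADRANTS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class CpgSelection:
    """CpGs retained for averaging (the grey region of a profile plot)."""

    threshold_fraction: float
    selected: Tuple[int, ...]
    max_level: float
    max_index: int
    source: str = ""

    @property
    def threshold(self) -> float:
        return self.threshold_fraction * self.max_level


def select_cpgs(
    on_profile: MethylationProfile,
    threshold_fraction: float = 0.5,
    source: str = "",
    baseline_profile: Optional[MethylationProfile] = None,
    exclude_interval: Optional[Tuple[int, int]] = None,
) -> CpgSelection:
    """Select CpGs with level >= ``threshold_fraction`` x the maximum level
    on the guide-treated on-target allele.  Uncovered CpGs never qualify.

    ``baseline_profile`` switches the criterion from absolute levels to
    gains over that baseline; ``exclude_interval`` drops CpGs inside a
    (guide) interval from the selection.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must be in (0, 1]")
    levels = on_profile.levels
    if baseline_profile is not None:
        levels = levels - baseline_profile.levels
    if exclude_interval is not None:
        s, e = exclude_interval
        levels = np.array(
            [
                np.nan if s <= p < e else lv
                for p, lv in zip(on_profile.cpg_positions, levels)
            ]
        )
    if np.all(np.isnan(levels)):
        raise ValueError("no covered CpGs; cannot select")
    max_index = int(np.nanargmax(levels))
    max_level = float(levels[max_index])
    thr = threshold_fraction * max_level
    selected = tuple(
        int(i) for i, lv in enumerate(levels) if not np.isnan(lv) and lv >= thr
    )
    return CpgSelection(
        threshold_fraction=threshold_fraction,
        selected=selected,
        max_level=max_level,
        max_index=max_index,
        source=source,
    )


@dataclass
class AsmResult:
    """ASM efficiency/specificity summary for one experiment.

    ``asm_delta`` is in percentage points; ``asm_ratio`` is dimensionless and
    ``None`` (flagged) when the off-target gain is not positive.
    """

    locus_name: str
    on_allele: str
    selection: CpgSelection
    mean_levels: Dict[Tuple[str, str], float]  # (condition, allele) -> mean
    gain_on: float
    gain_off: float
    asm_delta: float
    asm_ratio: Optional[float]
    ratio_undefined: bool = False
    footprint_score: Optional[float] = None
    outcome: Optional[str] = None
    outcome_flagged: bool = False

    def as_row(self) -> dict:
        return {
            "locus": self.locus_name,
            "on_allele": self.on_allele,
            "n_selected_cpgs": len(self.selection.selected),
            "gain_on": self.gain_on,
            "gain_off": self.gain_off,
            "asm_delta": self.asm_delta,
            "asm_ratio": self.asm_ratio,
            "footprint_score": self.footprint_score,
            "outcome": self.outcome,
        }


def asm_scores(
    profiles: Mapping[Tuple[str, str], MethylationProfile],
    selection: CpgSelection,
    on_allele: str = "allele1",
    baseline_condition: str = "untransfected",
    locus_name: str = "",
) -> AsmResult:
    """Compute ASM Δ% and ratio from per-condition per-allele profiles.

    ``profiles`` maps ``(condition, allele)`` to a profile; the guide-treated
    and baseline conditions must be present for both alleles.  Scrambled
    means, when provided, ride along as the specificity control.
    """
    off_allele = "allele2" if on_allele == "allele1" else "allele1"
    for key in (
        (baseline_condition, on_allele),
        (baseline_condition, off_allele),
        ("guide", on_allele),
        ("guide", off_allele),
    ):
        if key not in profiles:
            raise ValueError(f"missing profile for {key}")
    sel = list(selection.selected)
    means = {key: prof.mean_level(sel) for key, prof in profiles.items()}
    gain_on = means[("guide", on_allele)] - means[(baseline_condition, on_allele)]
    gain_off = means[("guide", off_allele)] - means[(baseline_condition, off_allele)]
    delta = (gain_on - gain_off) * 100.0
    if gain_off > 0:
        ratio: Optional[float] = gain_on / gain_off
        undefined = False
    else:
        ratio, undefined = None, True
    return AsmResult(
        locus_name=locus_name,
        on_allele=on_allele,
        selection=selection,
        mean_levels=means,
        gain_on=gain_on,
        gain_off=gain_off,
        asm_delta=delta,
        asm_ratio=ratio,
        ratio_undefined=undefined,
    )


def footprint_score(
    on_profile: MethylationProfile,
    guide_interval: Tuple[int, int],
    flank_cpgs: int = 3,
) -> Optional[float]:
    """Protection of the sgRNA binding site by bound dCas9.

    Score = mean level of the nearest ``flank_cpgs`` covered CpGs on each
    side of the guide interval minus the mean level inside it; positive
    scores indicate a footprint.  ``None`` when no CpG lies inside.
    """
    s, e = guide_interval
    levels = on_profile.levels
    pos = on_profile.cpg_positions
    inside = [i for i, p in enumerate(pos) if s <= p < e and not np.isnan(levels[i])]
    if not inside:
        return None
    left = [i for i, p in enumerate(pos) if p < s and not np.isnan(levels[i])]
    right = [i for i, p in enumerate(pos) if p >= e and not np.isnan(levels[i])]
    flank = left[-flank_cpgs:] + right[:flank_cpgs]
    if not flank:
        return None
    return float(np.mean(levels[flank]) - np.mean(levels[inside]))


@dataclass
class StabilityResult:
    """Retention of delivered methylation over a timecourse.

    ``retention[day]`` is the selected-CpG mean level on that day as a
    percentage of the day-3 level; retention on day 3 is 100 by construction.
    """

    locus_name: str
    reference_day: int
    mean_levels: Dict[int, float]
    retention: Dict[int, float] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        days = sorted(self.mean_levels)
        return pd.DataFrame(
            {
                "day": days,
                "mean_level": [self.mean_levels[d] for d in days],
                "retention_pct": [self.retention[d] for d in days],
            }
        )


def stability_retention(
    timecourse: Mapping[int, MethylationProfile],
    selection: CpgSelection,
    reference_day: int = 3,
    baseline: Optional[Mapping[int, MethylationProfile]] = None,
    use_gains: bool = False,
    locus_name: str = "",
) -> StabilityResult:
    """Per-day retention of the on-target methylation relative to day 3.

    Uses absolute levels by default; with ``use_gains`` the per-day baseline
    profile is subtracted first.  The CpG selection is the day-3 selection,
    frozen across timepoints.
    """
    if reference_day not in timecourse:
        raise ValueError(f"reference day {reference_day} missing from timecourse")
    sel = list(selection.selected)
    means: Dict[int, float] = {}
    for day, prof in timecourse.items():
        m = prof.mean_level(sel)
        if use_gains:
            if baseline is None or day not in baseline:
                raise ValueError("use_gains requires a baseline profile per day")
            m -= baseline[day].mean_level(sel)
        means[day] = m
    ref = means[reference_day]
    if not ref > 0:
        raise ValueError("reference-day mean methylation is zero; retention undefined")
    retention = {day: 100.0 * m / ref for day, m in means.items()}
    return StabilityResult(
        locus_name=locus_name,
        reference_day=reference_day,
        mean_levels=means,
        retention=retention,
    )


def classify_outcome(
    asm: AsmResult,
    delta_cut: float = 25.0,
    ratio_cut: float = 3.0,
) -> AsmResult:
    """Assign the Δ/ratio scatter quadrant (I best ... III worst).

    Quadrant I: Δ and ratio both above their cuts; II: ratio only;
    IV: Δ only; III: neither.  With an undefined ratio the call falls back to
    Δ alone and is flagged.
    """
    if asm.asm_delta is None or np.isnan(asm.asm_delta):
        raise ValueError("asm_delta missing; cannot classify")
    d_ok = asm.asm_delta >= delta_cut
    if asm.asm_ratio is None:
        asm.outcome = "IV" if d_ok else "III"
        asm.outcome_flagged = True
        return asm
    r_ok = asm.asm_ratio >= ratio_cut
    asm.outcome = {(True, True): "I", (False, True): "II", (True, False): "IV", (False, False): "III"}[
        (d_ok, r_ok)
    ]
    asm.outcome_flagged = False
    return asm


def scatter_frame(results: Sequence[AsmResult]) -> pd.DataFrame:
    """Δ/ratio scatter data, one row per experiment."""
    return pd.DataFrame(
        [
            {
                "locus": r.locus_name,
                "asm_delta": r.asm_delta,
                "asm_ratio": r.asm_ratio,
                "outcome": r.outcome,
            }
            for r in results
        ]
    )


def scatter_plot(results: Sequence[AsmResult], path, delta_cut: float = 25.0, ratio_cut: float = 3.0):
    """Write the Δ/ratio scatter (quadrant plot) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = scatter_frame(results).dropna(subset=["asm_ratio"])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(df["asm_delta"], df["asm_ratio"], c="tab:blue")
    for _, row in df.iterrows():
        ax.annotate(row["locus"], (row["asm_delta"], row["asm_ratio"]), fontsize=7)
    ax.axvline(delta_cut, ls="--", c="grey")
    ax.axhline(ratio_cut, ls="--", c="grey")
    ax.set_xlabel("ASM Δ (%)")
    ax.set_ylabel("ASM ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
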