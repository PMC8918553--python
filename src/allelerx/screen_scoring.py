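"""Fluorescence-reporter screen scoring.

A knockdown screen transfects cells with (i) the effector, (ii) one of two
mCherry reporters carrying the wild-type or mutant target sequence, and
(iii) either a targeting guide or a non-targeting (NT) control guide.
Reporter fluorescence intensity, already region-averaged per well, is the
readout. Per guide and reporter the knockdown ratio is

    ratio = mean(guide-well intensity) / mean(NT-well intensity)

and the allele-specificity score is ratio_MUT / ratio_WT — lower means
more mutant-selective knockdown. Percent decrease is 100 x (1 - ratio).

Two aggregation modes are provided. The default, ``mean_of_wells``, divides
the two well means (the ratio of averaged intensities). The alternative,
``per_replicate``, averages per-replicate ratios guide_i / NT_i matched by
replicate index; instruments that drift between replicates can make the
two disagree, so both are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

NT_GUIDE = "NT"
REPORTERS = ("MUT", "WT")

AggregationMode = Literal["mean_of_wells", "per_replicate"]


class ScreenError(ValueError):
    """Invalid screen dataset or unscorable request."""


@dataclass(frozen=True)
class WellMeasurement:
    """One well: guide (or "NT"), reporter allele, replicate, intensity."""

    guide_id: str
    reporter: str
    replicate: int
    intensity: float

    def __post_init__(self) -> None:
        if self.reporter not in REPORTERS:
            raise ScreenError(f"reporter must be one of {REPORTERS}, got {self.reporter!r}")
        if self.replicate < 1:
            raise ScreenError("replicate index must be >= 1")
        if self.intensity < 0:
            raise ScreenError("intensity must be nonnegative")


@dataclass(frozen=True)
class GuideScore:
    """Per-guide screen summary.

    ``specificity = ratio_mut / ratio_wt``; ``pct_decrease_x = 100 * (1 -
    ratio_x)``. The SD fields are the sample SD of per-replicate ratios
    (guide well / NT mean), reported alongside each mean; None when a cell
    has a single replicate.
    """

    guide_id: str
    ratio_mut: float
    ratio_wt: float
    specificity: float
    pct_decrease_mut: float
    pct_decrease_wt: float
    ratio_mut_sd: float | None
    ratio_wt_sd: float | None
    n_mut: int
    n_wt: int


def wells_to_frame(wells: Iterable[WellMeasurement]) -> pd.DataFrame:
    """Tabulate wells, enforcing (guide, reporter, replicate) uniqueness."""
    df = pd.DataFrame(
        [(w.guide_id, w.reporter, w.replicate, w.intensity) for w in wells],
        columns=["guide_id", "reporter", "replicate", "intensity"],
    )
    return validate_wells(df)


def validate_wells(df: pd.DataFrame) -> pd.DataFrame:
    required = {"guide_id", "reporter", "replicate", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ScreenError(f"wells table missing column(s): {sorted(missing)}")
    if (df["intensity"] < 0).any():
        raise ScreenError("negative intensity in wells table")
    bad = set(df["reporter"]) - set(REPORTERS)
    if bad:
        raise ScreenError(f"unknown reporter label(s): {sorted(bad)}")
    dup = df.duplicated(subset=["guide_id", "reporter", "replicate"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ScreenError(
            "duplicate well: "
            f"({row['guide_id']}, {row['reporter']}, replicate {row['replicate']})"
        )
    return df


def _cell(df: pd.DataFrame, guide_id: str, reporter: str) -> pd.DataFrame:
    cell = df[(df["guide_id"] == guide_id) & (df["reporter"] == reporter)]
    if cell.empty:
        raise ScreenError(f"no wells for guide {guide_id!r}, reporter {reporter!r}")
    return cell


def knockdown_ratio(
    wells: pd.DataFrame,
    guide_id: str,
    reporter: str,
    nt_id: str = NT_GUIDE,
    mode: AggregationMode = "mean_of_wells",
) -> float:
    """Guide/NT intensity ratio for one reporter.

    ``mean_of_wells``: mean guide intensity over mean NT intensity.
    ``per_replicate``: mean over replicates of guide_i / NT_i, matched by
    replicate index (requires identical replicate sets).
    """
    guide = _cell(wells, guide_id, reporter)
    nt = _cell(wells, nt_id, reporter)
    if mode == "mean_of_wells":
        nt_mean = nt["intensity"].mean()
        if nt_mean == 0:
            raise ScreenError(f"NT mean intensity is zero for reporter {reporter}")
        return float(guide["intensity"].mean() / nt_mean)
    g = guide.set_index("replicate")["intensity"]
    n = nt.set_index("replicate")["intensity"]
    if set(g.index) != set(n.index):
        raise ScreenError(
            f"per_replicate mode needs matching replicate sets for "
            f"{guide_id!r} and {nt_id!r} ({reporter})"
        )
    if (n == 0).any():
        raise ScreenError(f"zero NT intensity in a replicate for reporter {reporter}")
    return float((g / n.reindex(g.index)).mean())


def percent_decrease(ratio: float) -> float:
    """100 x (1 - ratio); negative when expression increased."""
    if ratio < 0:
        raise ScreenError("ratio must be nonnegative")
    return 100.0 * (1.0 - ratio)


def specificity_score(
    wells: pd.DataFrame,
    guide_id: str,
    nt_id: str = NT_GUIDE,
    mode: AggregationMode = "mean_of_wells",
) -> float:
    """ratio_MUT / ratio_WT; lower values mean more mutant-specific."""
    ratio_mut = knockdown_ratio(wells, guide_id, "MUT", nt_id, mode)
    ratio_wt = knockdown_ratio(wells, guide_id, "WT", nt_id, mode)
    if ratio_wt == 0:
        raise ScreenError(
            f"complete WT knockdown for guide {guide_id!r}: specificity undefined"
        )
    return ratio_mut / ratio_wt


def score_guide(
    wells: pd.DataFrame,
    guide_id: str,
    nt_id: str = NT_GUIDE,
    mode: AggregationMode = "mean_of_wells",
) -> GuideScore:
    ratios: dict[str, float] = {}
    sds: dict[str, float | None] = {}
    ns: dict[str, int] = {}
    for reporter in REPORTERS:
        ratios[reporter] = knockdown_ratio(wells, guide_id, reporter, nt_id, mode)
        guide = _cell(wells, guide_id, reporter)
        nt_mean = _cell(wells, nt_id, reporter)["intensity"].mean()
        per_rep = guide["intensity"] / nt_mean
        ns[reporter] = len(per_rep)
        sds[reporter] = float(per_rep.std(ddof=1)) if len(per_rep) > 1 else None
    if ratios["WT"] == 0:
        raise ScreenError(
            f"complete WT knockdown for guide {guide_id!r}: specificity undefined"
        )
    return GuideScore(
        guide_id=guide_id,
        ratio_mut=ratios["MUT"],
        ratio_wt=ratios["WT"],
        specificity=ratios["MUT"] / ratios["WT"],
        pct_decrease_mut=percent_decrease(ratios["MUT"]),
        pct_decrease_wt=percent_decrease(ratios["WT"]),
        ratio_mut_sd=sds["MUT"],
        ratio_wt_sd=sds["WT"],
        n_mut=ns["MUT"],
        n_wt=ns["WT"],
    )


def rank_guides(
    wells: pd.DataFrame,
    nt_id: str = NT_GUIDE,
    mode: AggregationMode = "mean_of_wells",
) -> list[GuideScore]:
    """Score every non-NT guide, ascending by specificity.

    Ties break by ascending ratio_mut, then lexicographic guide id. The
    first-ranked guide is the screen's most mutant-specific candidate.
    """
    validate_wells(wells)
    guide_ids = sorted(set(wells["guide_id"]) - {nt_id})
    if not guide_ids:
        raise ScreenError("no scorable guides in dataset")
    scores = [score_guide(wells, g, nt_id, mode) for g in guide_ids]
    scores.sort(key=lambda s: (s.specificity, s.ratio_mut, s.guide_id))
    return scores


def scores_to_frame(scores: Iterable[GuideScore]) -> pd.DataFrame:
    rows = [
        {
            "guide_id": s.guide_id,
            "ratio_mut": s.ratio_mut,
            "ratio_wt": s.ratio_wt,
            "specificity": s.specificity,
            "pct_decrease_mut": s.pct_decrease_mut,
            "pct_decrease_wt": s.pct_decrease_wt,
            "ratio_mut_sd": np.nan if s.ratio_mut_sd is None else s.ratio_mut_sd,
            "ratio_wt_sd": np.nan if s.ratio_wt_sd is None else s.ratio_wt_sd,
            "n_mut": s.n_mut,
            "n_wt": s.n_wt,
        }
        for s in scores
    ]
    return pd.DataFrame(rows)
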