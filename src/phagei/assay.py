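"""Efficiency-of-plating (EOP) analysis of spot-titration plaque counts.

A phage stock is serially diluted 10-fold and a small fixed volume
(default 2 uL) of each dilution is spotted on a bacterial lawn.  The
titer is read from the least-diluted spot whose plaque count falls in a
countable range (default 3-30 per spot); if every spot is clear of
plaques, only a detection-limit upper bound on the titer is known.

EOP is the ratio of the titer on the test lawn (expressing a
gene-targeting crRNA) to the titer on a control lawn (nontargeting
crRNA).  When no plaques form on the test lawn the EOP itself is
censored and reported as an upper bound ("<x").

Classification: knockdown of an essential gene suppresses plating by
three or more orders of magnitude, so genes with mean EOP <= 1e-3 are
called essential (E), >= 1e-2 nonessential (NE), and the decade in
between is an intermediate band for partial plating defects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpotCount",
    "Titer",
    "EOPValue",
    "EOPResult",
    "AssayError",
    "titer_from_spots",
    "compute_eop",
    "aggregate_and_classify",
    "analyze_counts_table",
    "read_counts_tsv",
]

DEFAULT_SPOT_VOLUME_UL = 2.0
DEFAULT_COUNT_RANGE = (3, 30)
DEFAULT_THRESHOLD = 1e-3
LAWN_CLEARED = -1  # sentinel plaque count for a fully cleared spot


class AssayError(ValueError):
    """Raised when a titration cannot be interpreted."""


@dataclass(frozen=True)
class SpotCount:
    """One spotted dilution: 2 uL of a 10^-k dilution, with its plaque count.

    ``plaques`` is a non-negative integer, or :data:`LAWN_CLEARED` when the
    spot cleared the lawn entirely (too many plaques to resolve).
    """

    sample_id: str
    dilution_exponent: int
    plaques: int
    spot_volume_ul: float = DEFAULT_SPOT_VOLUME_UL

    def __post_init__(self) -> None:
        if self.dilution_exponent < 0:
            raise AssayError("dilution_exponent must be >= 0")
        if self.plaques < 0 and self.plaques != LAWN_CLEARED:
            raise AssayError("plaques must be >= 0 or the lawn-cleared sentinel")

    @property
    def lawn_cleared(self) -> bool:
        return self.plaques == LAWN_CLEARED


@dataclass(frozen=True)
class Titer:
    """A titer in PFU/mL; ``censored`` means only an upper bound is known."""

    pfu_per_ml: float
    censored: bool = False

    def __str__(self) -> str:
        return f"<{self.pfu_per_ml:.3g}" if self.censored else f"{self.pfu_per_ml:.3g}"


@dataclass(frozen=True)
class EOPValue:
    """One EOP replicate; ``censored`` means the value is an upper bound."""

    value: float
    censored: bool = False

    def __str__(self) -> str:
        return f"<{self.value:.3g}" if self.censored else f"{self.value:.3g}"


def titer_from_spots(
    counts: Sequence[SpotCount],
    count_range: tuple[int, int] = DEFAULT_COUNT_RANGE,
) -> Titer:
    """Titer from one sample's dilution series.

    Preference order: the least-diluted spot whose count is countable
    (within *count_range*); failing that, the least-diluted spot with at
    least one plaque (recorded counts outside the countable range are
    noisier but still informative); failing that, all spots are clear and
    a detection-limit bound is returned from the most concentrated spot.
    """
    if not counts:
        raise AssayError("no spots provided")
    volumes = {c.spot_volume_ul for c in counts}
    if len(volumes) > 1:
        raise AssayError("all spots of a sample must share spot_volume")
    vol_ml = volumes.pop() / 1000.0
    lo, hi = count_range
    spots = sorted(counts, key=lambda c: c.dilution_exponent)

    def titer_at(c: SpotCount) -> float:
        return c.plaques / (vol_ml * 10.0 ** -c.dilution_exponent)

    for c in spots:
        if not c.lawn_cleared and lo <= c.plaques <= hi:
            return Titer(titer_at(c))
    for c in spots:
        if not c.lawn_cleared and c.plaques > 0:
            return Titer(titer_at(c))
    if all(c.lawn_cleared for c in spots):
        raise AssayError(
            "every spot cleared the lawn; the sample is too concentrated -- "
            "extend the dilution series"
        )
    k_min = min(c.dilution_exponent for c in spots if not c.lawn_cleared)
    return Titer(1.0 / (vol_ml * 10.0 ** -k_min), censored=True)


def compute_eop(target: Titer, control: Titer) -> EOPValue:
    """EOP = target titer / control titer; censoring propagates from the
    target.  A censored control invalidates the assay."""
    if control.censored:
        raise AssayError("control titer is censored; assay invalid")
    if control.pfu_per_ml <= 0:
        raise AssayError("control titer must be positive")
    return EOPValue(target.pfu_per_ml / control.pfu_per_ml, censored=target.censored)


@dataclass
class EOPResult:
    """Aggregated EOP over replicates with the essentiality call."""

    locus_tag: str
    eop_replicates: list[EOPValue]
    eop_mean: float
    eop_sd: float
    censored: bool
    call: str  # "E", "NE", or "intermediate"
    gene_name: str | None = None

    def render_mean(self) -> str:
        return f"<{self.eop_mean:.1E}" if self.censored else f"{self.eop_mean:.1E}"


def _call_from_mean(mean: float, censored: bool, threshold: float) -> str:
    if mean <= threshold:
        return "E"
    if censored:
        # only an upper bound is known and it sits above the essential
        # threshold: the true EOP could be anywhere below it
        return "intermediate"
    if mean >= 10.0 * threshold:
        return "NE"
    return "intermediate"


def aggregate_and_classify(
    replicates: Sequence[EOPValue],
    threshold: float = DEFAULT_THRESHOLD,
    locus_tag: str = "",
    gene_name: str | None = None,
) -> EOPResult:
    """Aggregate replicate EOPs and call essentiality.

    Censored bounds are never averaged with measured values: when at
    least one replicate is uncensored the mean/SD use uncensored values
    only (with a warning if a censored bound contradicts them by sitting
    well below the measured mean); when all replicates are censored the
    mean of the bounds is itself reported as a bound.
    """
    if not replicates:
        raise AssayError("need at least one replicate")
    measured = [r.value for r in replicates if not r.censored]
    bounds = [r.value for r in replicates if r.censored]
    if measured:
        mean = float(np.mean(measured))
        sd = float(np.std(measured, ddof=1)) if len(measured) > 1 else 0.0
        censored = False
        if bounds and min(bounds) < mean / 10.0:
            warnings.warn(
                f"{locus_tag or 'sample'}: censored bound {min(bounds):.2g} "
                f"contradicts measured mean {mean:.2g}; using measured values",
                stacklevel=2,
            )
    else:
        mean = float(np.mean(bounds))
        sd = 0.0
        censored = True
    call = _call_from_mean(mean, censored, threshold)
    return EOPResult(
        locus_tag=locus_tag,
        eop_replicates=list(replicates),
        eop_mean=mean,
        eop_sd=sd,
        censored=censored,
        call=call,
        gene_name=gene_name,
    )


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------

COUNTS_COLUMNS = (
    "sample_id", "dilution_exponent", "plaques", "volume_uL", "replicate_id", "control_flag",
)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise AssayError(f"counts table missing columns {sorted(missing)}")
    return df


def analyze_counts_table(
    counts: pd.DataFrame,
    control_id: str | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    count_range: tuple[int, int] = DEFAULT_COUNT_RANGE,
) -> list[EOPResult]:
    """Full spot-count table -> per-gene EOP results.

    The table holds one row per (sample, replicate, dilution).  Control
    rows are identified by ``control_flag`` truthy or by *control_id*;
    target and control titers are paired within each replicate.
    """

    def is_control(row) -> bool:
        if control_id is not None and row.sample_id == control_id:
            return True
        return bool(row.control_flag)

    counts = counts.copy()
    counts["_ctrl"] = [is_control(r) for r in counts.itertuples(index=False)]
    control_rows = counts[counts["_ctrl"]]
    if control_rows.empty:
        raise AssayError("no control sample found in counts table")

    control_titers: dict[object, Titer] = {}
    for rep, grp in control_rows.groupby("replicate_id"):
        spots = [
            SpotCount(str(r.sample_id), int(r.dilution_exponent), int(r.plaques),
                      float(r.volume_uL))
            for r in grp.itertuples(index=False)
        ]
        control_titers[rep] = titer_from_spots(spots, count_range)

    results = []
    target_rows = counts[~counts["_ctrl"]]
    for sample, sample_grp in target_rows.groupby("sample_id", sort=False):
        reps = []
        for rep, grp in sample_grp.groupby("replicate_id"):
            if rep not in control_titers:
                warnings.warn(
                    f"{sample}: replicate {rep} has no control titration; skipped",
                    stacklevel=2,
                )
                continue
            spots = [
                SpotCount(str(r.sample_id), int(r.dilution_exponent), int(r.plaques),
                          float(r.volume_uL))
                for r in grp.itertuples(index=False)
            ]
            reps.append(compute_eop(titer_from_spots(spots, count_range),
                                    control_titers[rep]))
        if reps:
            results.append(
                aggregate_and_classify(reps, threshold, locus_tag=str(sample))
            )
    return results


def results_to_frame(results: Iterable[EOPResult]) -> pd.DataFrame:
    rows = [
        {
            "locus_tag": r.locus_tag,
            "gene": r.gene_name or "",
            "EOP_average": r.render_mean(),
            "SD": f"{r.eop_sd:.1E}",
            "call": r.call,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["locus_tag", "gene", "EOP_average", "SD", "call"])
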