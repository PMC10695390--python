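"""Golden-Gate-compatible spacer oligo pairs and order sheets.

Each designed spacer is ordered as two complementary oligos that anneal
into a duplex with 4-nt single-stranded 5' extensions for directional
ligation into the crRNA cassette:

* forward oligo: ``AGAT`` + spacer + ``G``
* reverse oligo: ``GAAAC`` + reverse-complement(spacer)

Annealed, the two strands share a 29-bp paired core (spacer + the G/C
pair) and present 4-nt 5' overhangs (``AGAT`` and ``GAAA``) on opposite
ends.  Only the string geometry is modelled here; the ligation chemistry
is the cloning protocol's business, not the design tool's.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genome_io import reverse_complement
from .guide_design import DesignReport

__all__ = ["OligoPair", "build_oligos", "export_order_sheet", "well_position"]

FORWARD_PREFIX = "AGAT"
FORWARD_SUFFIX = "G"
REVERSE_PREFIX = "GAAAC"


@dataclass(frozen=True)
class OligoPair:
    forward: str
    reverse: str
    spacer: str


def build_oligos(spacer: str, spacer_length: int = 28) -> OligoPair:
    """Build the forward/reverse oligo pair for one spacer."""
    spacer = spacer.upper()
    if len(spacer) != spacer_length:
        raise ValueError(
            f"spacer length {len(spacer)} != expected {spacer_length}"
        )
    if set(spacer) - set("ACGT"):
        raise ValueError(f"spacer contains non-ACGT characters: {spacer!r}")
    return OligoPair(
        forward=FORWARD_PREFIX + spacer + FORWARD_SUFFIX,
        reverse=REVERSE_PREFIX + reverse_complement(spacer),
        spacer=spacer,
    )


def well_position(index: int, rows: str = string.ascii_uppercase[:8], cols: int = 12) -> tuple[int, str]:
    """(plate number, well) for 0-based *index*, filling A1..A12, B1.. row-major."""
    per_plate = len(rows) * cols
    plate, pos = divmod(index, per_plate)
    r, c = divmod(pos, cols)
    return plate + 1, f"{rows[r]}{c + 1}"


def export_order_sheet(report: DesignReport, path: str | Path | None = None) -> pd.DataFrame:
    """One row per guide with plate/well assignment and both oligo sequences.

    Guides beyond 96 spill onto the next plate, restarting at A1.
    """
    if not report.guides:
        raise ValueError("design report contains no guides to order")
    rows = []
    for i, g in enumerate(report.guides):
        plate, well = well_position(i)
        pair = build_oligos(g.spacer, spacer_length=len(g.spacer))
        rows.append(
            {
                "plate": plate,
                "well": well,
                "locus_tag": g.locus_tag,
                "oligo_name_f": f"{g.locus_tag}_F",
                "oligo_name_r": f"{g.locus_tag}_R",
                "forward": pair.forward,
                "reverse": pair.reverse,
                "spacer": g.spacer,
            }
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
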