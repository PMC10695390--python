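"""Polarity-aware interpretation of CRISPRi essentiality calls.

A DNA-bound dCas12a/crRNA complex is a transcription roadblock: it
silences not only its target gene but every gene downstream on the same
transcript.  An "essential" readout is therefore only informative when
no gene downstream of the target in its transcriptional unit is itself
required — i.e. essentiality can only be assigned to the last required
gene on a transcript.  Conversely a nonessential readout upstream of a
required gene is anomalous (the roadblock should have been polar on the
downstream essential gene) and is flagged as readthrough.

Supplying a downstream gene product in trans (e.g. the lambda late-gene
activator Q from a plasmid) removes that gene from the set of downstream
blockers and lets upstream calls be re-evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TranscriptUnit",
    "CallInterpretation",
    "interpret",
    "informative_essential_set",
    "reconcile_complementation",
    "read_units_tsv",
    "interpretations_to_frame",
]

# status labels, ordered most->least conservative for multi-unit genes
_STATUS_RANK = {
    "potentially_polar": 0,
    "readthrough_anomaly": 1,
    "informative_essential": 2,
    "nonessential": 3,
}


@dataclass(frozen=True)
class TranscriptUnit:
    """An ordered list of genes transcribed 5'->3' from one promoter."""

    name: str
    genes: tuple[str, ...]

    def __init__(self, name: str, genes: Sequence[str]):
        genes = tuple(genes)
        if not genes:
            raise ValueError(f"unit {name!r} has no genes")
        if len(set(genes)) != len(genes):
            raise ValueError(f"unit {name!r} contains duplicate genes")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", genes)


@dataclass(frozen=True)
class CallInterpretation:
    locus_tag: str
    call: str  # "E" or "NE"
    status: str
    explanation: str


def _interpret_in_unit(
    unit: TranscriptUnit,
    calls: Mapping[str, str],
    complemented: frozenset[str],
) -> dict[str, tuple[str, str]]:
    """Per-gene (status, explanation) within one unit.

    Complemented genes are removed from consideration as downstream
    blockers and receive no status themselves in this evaluation.
    """
    members = [g for g in unit.genes if g not in complemented]
    out: dict[str, tuple[str, str]] = {}
    for i, gene in enumerate(members):
        call = calls.get(gene)
        if call is None:
            continue  # untested gene: no interpretation
        downstream_e = [g for g in members[i + 1 :] if calls.get(g) == "E"]
        if call == "E":
            if downstream_e:
                out[gene] = (
                    "potentially_polar",
                    f"E call in {unit.name} may be polar on downstream "
                    f"essential gene(s) {', '.join(downstream_e)}",
                )
            else:
                out[gene] = (
                    "informative_essential",
                    f"last required gene on transcript {unit.name}",
                )
        else:
            if downstream_e:
                out[gene] = (
                    "readthrough_anomaly",
                    f"NE call in {unit.name} despite downstream essential "
                    f"gene(s) {', '.join(downstream_e)}; roadblock readthrough?",
                )
            else:
                out[gene] = ("nonessential", f"NE with no downstream requirement in {unit.name}")
    return out


def interpret(
    calls: Mapping[str, str],
    units: Sequence[TranscriptUnit],
    complemented: Iterable[str] = (),
) -> list[CallInterpretation]:
    """Interpret per-gene E/NE calls over transcriptional units.

    Genes appearing in several units get the most conservative status
    across units (a roadblock on shared DNA blocks every transcript
    through it).  Genes with a call but in no unit are ``unplaced``.
    """
    complemented = frozenset(complemented)
    unit_members = {g for u in units for g in u.genes}
    unknown = complemented - unit_members
    if unknown:
        raise ValueError(f"complemented genes not found in any unit: {sorted(unknown)}")

    per_gene: dict[str, tuple[str, str]] = {}
    for unit in units:
        for gene, (status, expl) in _interpret_in_unit(unit, calls, complemented).items():
            if gene in per_gene:
                # conservative merge: a gene is only informative if it is
                # informative in every unit that carries it
                if _STATUS_RANK[status] < _STATUS_RANK[per_gene[gene][0]]:
                    per_gene[gene] = (status, expl)
            else:
                per_gene[gene] = (status, expl)

    out = []
    for gene, call in calls.items():
        if gene in complemented:
            continue
        if gene in per_gene:
            status, expl = per_gene[gene]
        elif gene in unit_members:
            status, expl = per_gene.get(gene, ("unplaced", "gene has no call in its unit"))
        else:
            status, expl = ("unplaced", "gene not assigned to any transcriptional unit")
        out.append(CallInterpretation(gene, call, status, expl))
    return out


def informative_essential_set(interps: Iterable[CallInterpretation]) -> set[str]:
    return {i.locus_tag for i in interps if i.status == "informative_essential"}


def reconcile_complementation(
    base_calls: Mapping[str, str],
    rerun_calls: Mapping[str, str],
    complemented_gene: str,
) -> dict[str, str]:
    """Compare calls before/after supplying *complemented_gene* in trans.

    A gene that read essential in the base assay but nonessential once
    the downstream product was supplied was a polar artifact; one that
    stays essential is confirmed; everything else is unchanged.
    """
    out = {}
    for gene, base in base_calls.items():
        if gene == complemented_gene:
            continue
        rerun = rerun_calls.get(gene)
        if rerun is None:
            import warnings

            warnings.warn(f"{gene}: missing from complementation rerun", stacklevel=2)
            out[gene] = "unchanged"
        elif base == "E" and rerun == "NE":
            out[gene] = "polar_artifact"
        elif base == "E" and rerun == "E":
            out[gene] = "confirmed_essential"
        else:
            out[gene] = "unchanged"
    return out


def read_units_tsv(path: str | Path) -> list[TranscriptUnit]:
    """Read transcriptional units from TSV (unit_name, rank, locus_tag)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"unit_name", "rank", "locus_tag"} - set(df.columns)
    if missing:
        raise ValueError(f"units table missing columns {sorted(missing)}")
    units = []
    for name, grp in df.groupby("unit_name", sort=False):
        grp = grp.sort_values("rank")
        units.append(TranscriptUnit(str(name), [str(t) for t in grp["locus_tag"]]))
    return units


def interpretations_to_frame(interps: Iterable[CallInterpretation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"locus_tag": i.locus_tag, "call": i.call, "status": i.status,
             "explanation": i.explanation}
            for i in interps
        ],
        columns=["locus_tag", "call", "status", "explanation"],
    )
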