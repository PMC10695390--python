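"""Benchmark reproduction against the published reference genomes.

The toolkit's design rule was benchmarked on two annotated RefSeq phage
genomes: lambda (NC_001416.1) and P1 (NC_005856.1).  Those sequences are
not redistributed with the package; :func:`ensure_reference` downloads
them once from NCBI into a local cache directory (network required) and
:func:`benchmark_design` then runs the default designer and compares the
untargetable gene set against the published roster (the NT rows of the
shipped essentiality tables), emitting per-gene diagnostics for any
discrepancy.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

import pandas as pd

from .genome_io import Genome
from .guide_design import DesignConfig, design_genome
from .synthetic import load_fixture

__all__ = [
    "LAMBDA_ACCESSION",
    "P1_ACCESSION",
    "expected_untargetable",
    "ensure_reference",
    "benchmark_design",
]

LAMBDA_ACCESSION = "NC_001416.1"
P1_ACCESSION = "NC_005856.1"

_EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=gbwithparts&retmode=text"
)

_FIXTURE_FOR = {LAMBDA_ACCESSION: "lambda_table1", P1_ACCESSION: "p1_table2"}


def expected_untargetable(accession: str) -> set[str]:
    """Gene names reported untestable (no canonical PAM) for a benchmark
    genome, read from the NT rows of the shipped essentiality table."""
    table = load_fixture(_FIXTURE_FOR[accession])
    out = set()
    for row in table.itertuples(index=False):
        if row.call_this_work.strip() == "NT":
            out.add(row.gene.strip() or row.locus_tag.strip())
    return out


def ensure_reference(
    accession: str, cache_dir: str | Path = "data/reference", timeout: float = 30.0
) -> Path:
    """Path to the cached GenBank file for *accession*, downloading from
    NCBI efetch if it is not cached yet."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"{accession}.gb"
    if path.exists() and path.stat().st_size > 0:
        return path
    url = _EFETCH.format(acc=accession)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except (urllib.error.URLError, OSError) as exc:
        raise RuntimeError(
            f"cannot download {accession} from NCBI ({exc}); place the GenBank "
            f"flat file at {path} manually to run the benchmark offline"
        ) from exc
    if b"LOCUS" not in data[:200]:
        raise RuntimeError(f"unexpected response fetching {accession} from NCBI")
    path.write_bytes(data)
    return path


def benchmark_design(
    genome: Genome, accession: str, config: DesignConfig = DesignConfig()
) -> pd.DataFrame:
    """Run the default designer and diff the untargetable set against the
    published roster; returns a per-gene diagnostics table."""
    report = design_genome(genome, config)
    expected = expected_untargetable(accession)
    rows = []
    by_name: dict[str, object] = {}
    for g in report.guides:
        by_name[g.gene_name or g.locus_tag] = g
    for u in report.untargetable:
        by_name[u.gene_name or u.locus_tag] = u
    observed_unt = {
        (u.gene_name or u.locus_tag) for u in report.untargetable
    }
    for name in sorted(expected | observed_unt):
        rows.append(
            {
                "gene": name,
                "expected_untargetable": name in expected,
                "observed_untargetable": name in observed_unt,
                "agrees": (name in expected) == (name in observed_unt),
            }
        )
    df = pd.DataFrame(rows, columns=[
        "gene", "expected_untargetable", "observed_untargetable", "agrees",
    ])
    df.attrs["n_targeted"] = len(report.guides)
    df.attrs["n_untargetable"] = len(report.untargetable)
    return df
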