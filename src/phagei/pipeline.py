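"""End-to-end orchestration: design -> oligos -> EOP -> polarity -> summary.

A :class:`RunConfig` names the inputs that are present; the pipeline runs
whichever stages those inputs enable and writes every intermediate table
plus a JSON summary into the output directory, along with the config
itself for provenance.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import assay, genome_io, guide_design, oligo_builder, polarity

logger = logging.getLogger("phagei")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    genome: str | None = None
    genome_format: str = "genbank"
    gene_table: str | None = None
    counts: str | None = None
    control_id: str | None = None
    units: str | None = None
    calls: str | None = None
    complemented: list[str] = field(default_factory=list)
    pam: str = "TTTV"
    spacer_length: int = 28
    window_lo: float = 0.20
    window_hi: float = 0.33
    threshold: float = 1e-3
    seed: int = 0
    outdir: str = "phagei_run"
    log_level: str = "INFO"

    def design_config(self) -> guide_design.DesignConfig:
        return guide_design.DesignConfig(
            pam_motif=self.pam,
            spacer_length=self.spacer_length,
            window_lo=self.window_lo,
            window_hi=self.window_hi,
        )

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages enabled by the config; returns the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_file(outdir / "config.json")
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)

    summary: dict = {"stages": []}
    calls: dict[str, str] = {}
    try:
        if config.genome:
            genome = genome_io.read_genome(
                config.genome, config.genome_format, table=config.gene_table
            )
            report = guide_design.design_genome(genome, config.design_config())
            report.to_tsv(outdir / "design.tsv")
            oligo_builder.export_order_sheet(report, outdir / "oligos.tsv")
            summary["stages"].append("design")
            summary["stages"].append("oligos")
            summary["n_genes"] = len(genome.features)
            summary["n_targeted"] = len(report.guides)
            summary["n_untargetable"] = len(report.untargetable)
            summary["untargetable"] = sorted(report.untargetable_tags)
            logger.info(
                "designed %d guides; %d untargetable",
                len(report.guides), len(report.untargetable),
            )
        if config.counts:
            counts = assay.read_counts_tsv(config.counts)
            results = assay.analyze_counts_table(
                counts, control_id=config.control_id, threshold=config.threshold
            )
            assay.results_to_frame(results).to_csv(
                outdir / "eop.tsv", sep="\t", index=False
            )
            calls = {r.locus_tag: r.call for r in results if r.call in ("E", "NE")}
            summary["stages"].append("eop")
            tally = {c: 0 for c in ("E", "NE", "intermediate")}
            for r in results:
                tally[r.call] += 1
            summary["calls"] = tally
            logger.info("EOP calls: %s", tally)
        elif config.calls:
            import pandas as pd

            df = pd.read_csv(config.calls, sep="\t", dtype=str)
            calls = {
                str(r.locus_tag): str(r.call)
                for r in df.itertuples(index=False)
                if str(r.call) in ("E", "NE")
            }
        if config.units and calls:
            units = polarity.read_units_tsv(config.units)
            interps = polarity.interpret(calls, units, config.complemented)
            polarity.interpretations_to_frame(interps).to_csv(
                outdir / "polarity.tsv", sep="\t", index=False
            )
            summary["stages"].append("polarity")
            summary["informative_essential"] = sorted(
                polarity.informative_essential_set(interps)
            )
            summary["readthrough_anomalies"] = sorted(
                i.locus_tag for i in interps if i.status == "readthrough_anomaly"
            )
        elif config.units:
            summary["notes"] = "units given but no calls available; polarity skipped"
        if not config.counts and not config.calls and config.genome:
            summary.setdefault(
                "notes", "assay stages skipped: no counts or calls provided"
            )
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
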