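"""Report rendering and the end-to-end pipeline runner.

All headline quantities in the reports (gene sizes, spacers, skews, RSCU)
are recomputed from coordinates and sequence, never echoed from the input
annotation; rounding happens only at render time.  Given the same config
and seed every report is byte-for-byte reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .annotation_io import (MitogenomeRecord, feature_length,
                            intergenic_spacer, read_feature_table,
                            read_genbank)
from .codon_usage import CodonUsageTable, GeneticCode, report_codon_table
from .composition import region_profiles
from .gene_order import (diff_report, encode_gene_order, ground_pattern,
                         render_linear_map)
from .phylo import Supermatrix, bootstrap_support
from .synthetic import GenomeSpec, generate_genome, simulate_alignment_on_tree


def summarize(record: MitogenomeRecord) -> pd.DataFrame:
    """Annotation-summary table: one row per feature, around the circle.

    Sizes and intergenic spacers are recomputed from the coordinates; the
    codon columns restate the annotation (they describe sequence content,
    which may be absent).
    """
    feats = sorted(record.features, key=lambda f: f.start)
    rows = []
    for f in feats:
        rows.append({
            "gene": f.name,
            "class": f.gene_class,
            "orientation": f.orientation or "-",
            "start": f.start,
            "end": f.end,
            "size_bp": feature_length(f, record.genome_length),
            "anticodon": f.anticodon or "-",
            "start_codon": f.start_codon or "-",
            "stop_codon": f.stop_codon or "-",
        })
    for row, f, nxt in zip(rows, feats, feats[1:] + feats[:1]):
        row["intergenic_nt"] = intergenic_spacer(f, nxt, record.genome_length)
    cols = ["gene", "class", "orientation", "start", "end", "size_bp",
            "intergenic_nt", "anticodon", "start_codon", "stop_codon"]
    return pd.DataFrame(rows)[cols]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: Optional[str] = None      # feature table / GenBank
    preset: Optional[str] = None          # e.g. "ku589292-like"
    region_strand: str = "coding"         # "coding" | "J"
    pct_decimals: int = 1
    skew_decimals: int = 3
    rscu_decimals: int = 2
    genetic_code: int = 5
    reference_order: str = "pancrustacean"
    bootstrap_replicates: int = 100
    seed: Optional[int] = None
    out_dir: str = "mitocomp_out"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


#: 6-taxon demonstration tree used by the pipeline's phylogeny stage when
#: run from a single simulated record: two cherries nested inside an
#: outgroup, with internal branches long enough for clear support.
DEMO_TREE = ("((sesarmid_A:0.05,sesarmid_B:0.05):0.10,"
             "(varunid_A:0.06,varunid_B:0.06):0.10,"
             "(grapsid:0.15,outgroup:0.30):0.05);")


def load_record(config: RunConfig) -> MitogenomeRecord:
    if config.input_path:
        p = Path(config.input_path)
        if p.suffix.lower() in (".gb", ".gbk", ".genbank"):
            return read_genbank(p)
        return read_feature_table(p)
    if config.preset:
        if config.seed is None:
            raise ValueError("simulation preset requires a seed")
        if config.preset.lower() in ("ku589292-like", "csinensis-like"):
            return generate_genome(GenomeSpec.ku589292_like(seed=config.seed))
        raise ValueError(f"unknown preset {config.preset!r}")
    raise ValueError("config needs either input_path or preset")


def run_pipeline(config: RunConfig) -> dict:
    """Annotation -> composition -> codon usage -> gene order -> phylogeny.

    Writes the five stage reports plus a machine-readable ``summary.json``
    (versions, config, seed, headline numbers) into ``config.out_dir`` and
    returns the summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"tool": "mitocomp", "version": __version__,
                     "config": asdict(config)}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # tag the failing stage
                raise RuntimeError(f"[{name}] {exc}") from exc
        return deco

    record = stage("annotation")(lambda: load_record(config))
    ann = summarize(record)
    ann.to_csv(out / "annotation_summary.tsv", sep="\t", index=False)
    summary["annotation"] = {
        "accession": record.accession,
        "genome_length_bp": record.genome_length,
        "n_features": len(record.features),
    }

    def _composition():
        profs = region_profiles(record, strand=config.region_strand)
        df = pd.DataFrame([
            p.as_row(config.pct_decimals, config.skew_decimals)
            for p in profs.values()])
        df.to_csv(out / "composition.tsv", sep="\t", index=False)
        g = profs["genome"]
        return {"at_content_pct": round(g.at_content, config.pct_decimals),
                "at_skew": round(g.at_skew, config.skew_decimals),
                "gc_skew": round(g.gc_skew, config.skew_decimals)}
    summary["composition"] = stage("composition")(_composition)

    def _codon():
        usage = CodonUsageTable.from_record(
            record, GeneticCode.from_ncbi_id(config.genetic_code))
        df = report_codon_table(usage, decimals=config.rscu_decimals)
        df.to_csv(out / "codon_usage.tsv", sep="\t", index=False)
        return {"n_codons": int(df["count"].sum()),
                "n_genes": len(usage.genes)}
    summary["codon_usage"] = stage("codon-usage")(_codon)

    def _order():
        order = encode_gene_order(record)
        report = diff_report(order, ground_pattern())
        text = (render_linear_map(order)
                + "\n\nvs pancrustacean ground pattern:\n"
                + f"breakpoints: {report.breakpoints}\n"
                + "".join(f"- {e.kind}: {', '.join(e.genes)} ({e.detail})\n"
                          for e in report.events))
        (out / "gene_order.txt").write_text(text)
        return {"breakpoints": report.breakpoints,
                "events": [{"kind": e.kind, "genes": list(e.genes)}
                           for e in report.events],
                "displaced": sorted(report.displaced)}
    summary["gene_order"] = stage("gene-order")(_order)

    def _phylo():
        if config.seed is None:
            raise ValueError("phylogeny stage requires a seed")
        aln = simulate_alignment_on_tree(DEMO_TREE, 5_000,
                                         seed=config.seed + 1)
        matrix = Supermatrix(taxa=sorted(aln),
                             sequences=[aln[t] for t in sorted(aln)])
        tree = bootstrap_support(matrix, config.bootstrap_replicates,
                                 seed=config.seed + 2)
        newick = str(tree).strip()
        (out / "tree.nwk").write_text(newick + "\n")
        supports = [getattr(n, "bootstrap", None)
                    for n in tree.non_tips(include_self=False)]
        return {"taxa": matrix.taxa,
                "supports": [s for s in supports if s is not None]}
    summary["phylogeny"] = stage("phylogeny")(_phylo)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
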