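"""Format readers/writers, declarative pipeline configuration and runner.

Sequence I/O goes through Biopython; tables are plain TSV; reports are
JSON.  The pipeline runner ties the network-analysis stages together
(simulate -> build network -> statistics -> size estimate) from a single
JSON configuration document with a global seed, and emits a manifest
with a checksum per output so identical configurations can be verified
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from . import ampdiv, homnet, netstats, synthgen
from .popgen import MarkerAlignment, QpcrCurve
from .synthgen import ReadRecord

logger = logging.getLogger("cytohet")


# ---------------------------------------------------------------------------
# sequence I/O


def read_sequences(path: str | Path, fmt: str | None = None) -> list[ReadRecord]:
    """Read FASTA/FASTQ into records (ids unique, sequences uppercased).

    ``fmt`` defaults from the file extension.  Malformed records raise a
    ValueError mentioning the file and the underlying parser error.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "fastq" if suffix in {".fastq", ".fq"} else "fasta"
    records: list[ReadRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), fmt):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate record id {rec.id}")
            seen.add(rec.id)
            qual = None
            if fmt == "fastq":
                scores = rec.letter_annotations["phred_quality"]
                qual = "".join(chr(33 + q) for q in scores)
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id) :].strip()
            records.append(
                ReadRecord(id=rec.id, seq=str(rec.seq).upper(), qual=qual,
                           description=desc)
            )
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err
    return records


def write_fasta(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(f"{header}\n{r.seq}\n")


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.qual is None or len(r.qual) != len(r.seq):
                raise ValueError(f"record {r.id} lacks matching quality string")
            header = f"@{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(f"{header}\n{r.seq}\n+\n{r.qual}\n")


def write_alleles_fasta(table: ampdiv.AlleleTable, path: str | Path) -> None:
    """Allele FASTA with ``;size=N`` abundance annotations."""
    with open(path, "w") as fh:
        for i, allele in enumerate(table.alleles):
            fh.write(f">allele{i:04d};size={allele.count}\n{allele.sequence}\n")


def read_alleles_fasta(path: str | Path) -> ampdiv.AlleleTable:
    alleles = []
    for rec in read_sequences(path, "fasta"):
        count = 1
        for part in rec.id.split(";"):
            if part.startswith("size="):
                count = int(part[5:])
        alleles.append(
            ampdiv.Allele(sequence=rec.seq, count=count, member_read_ids=[])
        )
    return ampdiv.AlleleTable(alleles=alleles)


def read_marker_alignment(path: str | Path) -> MarkerAlignment:
    """Aligned marker FASTA; ``;size=N`` id suffixes carry abundances."""
    ids, seqs, counts = [], [], []
    for rec in read_sequences(path, "fasta"):
        count = 1
        rid = rec.id
        for part in rec.id.split(";"):
            if part.startswith("size="):
                count = int(part[5:])
                rid = rec.id.split(";")[0]
        ids.append(rid)
        seqs.append(rec.seq)
        counts.append(count)
    return MarkerAlignment(ids=ids, sequences=seqs, counts=counts)


# ---------------------------------------------------------------------------
# tables


def write_edges_tsv(edges: Sequence[homnet.HomologyEdge], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "read_a": [e.read_a for e in edges],
            "read_b": [e.read_b for e in edges],
            "identical_positions": [e.identical_positions for e in edges],
            "shorter_len": [e.shorter_len for e in edges],
            "pid": [round(e.pid, 4) for e in edges],
            "evalue": [f"{e.evalue:.3e}" for e in edges],
            "strand": [e.strand for e in edges],
            "a_start": [e.a_start for e in edges],
            "a_end": [e.a_end for e in edges],
            "b_start": [e.b_start for e in edges],
            "b_end": [e.b_end for e in edges],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_edges_tsv(path: str | Path) -> list[homnet.HomologyEdge]:
    df = pd.read_csv(path, sep="\t")
    return [
        homnet.HomologyEdge(
            read_a=str(row.read_a),
            read_b=str(row.read_b),
            identical_positions=int(row.identical_positions),
            shorter_len=int(row.shorter_len),
            pid=float(row.pid),
            evalue=float(row.evalue),
            strand=str(row.strand),
            a_start=int(row.a_start),
            a_end=int(row.a_end),
            b_start=int(row.b_start),
            b_end=int(row.b_end),
        )
        for row in df.itertuples()
    ]


def write_clusters_tsv(result: homnet.NetworkResult, path: str | Path) -> None:
    rows = []
    for cluster in result.clusters:
        for rid in sorted(cluster.member_read_ids):
            rows.append((rid, cluster.cluster_id))
    for rid in result.singletons:
        rows.append((rid, "singleton"))
    pd.DataFrame(rows, columns=["read_id", "cluster_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_qpcr_tsv(path: str | Path) -> dict[str, QpcrCurve]:
    """qPCR TSV (assay, replicate, concentration, ct) -> curve per assay."""
    import numpy as np

    df = pd.read_csv(path, sep="\t")
    required = {"assay", "concentration", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    curves = {}
    for assay, sub in df.groupby("assay"):
        curves[str(assay)] = QpcrCurve(
            log10_conc=list(np.log10(sub["concentration"].astype(float))),
            ct=list(sub["ct"].astype(float)),
        )
    return curves


# ---------------------------------------------------------------------------
# pipeline configuration


_SECTION_TYPES = {
    "genome": synthgen.GenomeSpec,
    "reads": synthgen.RunConfig,
    "edge_policy": homnet.EdgePolicy,
}
_POPULATION_KEYS = {"n_haplotypes", "divergence", "proportions", "seed"}
_TOP_KEYS = {"seed", "outdir", "genome", "population", "reads", "edge_policy"}


@dataclass
class PipelineConfig:
    """Declarative configuration of the network-analysis pipeline.

    Round-trips losslessly through JSON; unknown keys anywhere are
    rejected.  The global ``seed`` offsets every stage seed so one
    integer reproduces the whole run.
    """

    seed: int
    outdir: str
    genome: dict[str, Any]
    population: dict[str, Any] = field(default_factory=dict)
    reads: dict[str, Any] = field(default_factory=dict)
    edge_policy: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "PipelineConfig":
        unknown = set(doc) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for section, typ in _SECTION_TYPES.items():
            allowed = {f.name for f in dataclasses.fields(typ)}
            bad = set(doc.get(section, {})) - allowed
            if bad:
                raise ValueError(
                    f"unknown key(s) in '{section}': {', '.join(sorted(bad))}"
                )
        bad = set(doc.get("population", {})) - _POPULATION_KEYS
        if bad:
            raise ValueError(
                f"unknown key(s) in 'population': {', '.join(sorted(bad))}"
            )
        return cls(
            seed=int(doc.get("seed", 0)),
            outdir=str(doc.get("outdir", ".")),
            genome=dict(doc.get("genome", {})),
            population=dict(doc.get("population", {})),
            reads=dict(doc.get("reads", {})),
            edge_policy=dict(doc.get("edge_policy", {})),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute simulate -> net-build -> net-stats -> genome-size.

    Returns (and writes) a manifest listing every output file with its
    sha256 checksum plus the full parameter document; identical
    configurations produce byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome_kwargs = dict(config.genome)
    genome_kwargs.setdefault("seed", config.seed)
    spec = synthgen.GenomeSpec(**genome_kwargs)
    logger.info("simulating genome: length=%d gc=%.3f", spec.length, spec.gc)
    genome = synthgen.simulate_genome(spec)

    pop_kwargs = dict(config.population)
    pop_kwargs.setdefault("n_haplotypes", 1)
    pop_kwargs.setdefault("divergence", 0.0)
    pop_kwargs.setdefault("seed", config.seed + 1)
    pool = synthgen.simulate_nucleus_population(genome, **pop_kwargs)

    read_kwargs = dict(config.reads)
    read_kwargs.setdefault("seed", config.seed + 2)
    cfg = synthgen.RunConfig(**read_kwargs)
    logger.info("simulating %d reads", cfg.n_reads)
    records, truth = synthgen.simulate_reads(pool, cfg)

    policy = homnet.EdgePolicy(**config.edge_policy)
    logger.info("building similarity network over %d reads", len(records))
    edges = homnet.find_homologous_pairs(records, policy)
    network = homnet.build_network(records, edges)
    logger.info(
        "network: %d clusters, %d singletons, %d edges",
        len(network.clusters), len(network.singletons), len(edges),
    )

    summary = netstats.summarize_run(network)
    size = netstats.estimate_min_genome_size(network, records)

    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fasta"
    write_fasta(
        [ReadRecord(id="genome", seq=genome)]
        + [
            ReadRecord(id=f"h{i}", seq=h)
            for i, h in enumerate(pool.haplotypes)
        ],
        paths["genome"],
    )
    paths["reads"] = outdir / "reads.fastq"
    write_fastq(records, paths["reads"])
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["edges"] = outdir / "edges.tsv"
    write_edges_tsv(edges, paths["edges"])
    paths["clusters"] = outdir / "clusters.tsv"
    write_clusters_tsv(network, paths["clusters"])
    paths["cluster_stats"] = outdir / "cluster_stats.tsv"
    netstats.per_cluster_table(network).to_csv(
        paths["cluster_stats"], sep="\t", index=False
    )
    paths["pid_histogram"] = outdir / "pid_histogram.tsv"
    netstats.pid_histogram(network).to_csv(
        paths["pid_histogram"], sep="\t", index=False
    )
    paths["summary"] = outdir / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(
            {
                "run": dataclasses.asdict(summary),
                "genome_size": dataclasses.asdict(size),
            },
            fh,
            indent=2,
            sort_keys=True,
        )

    manifest = {
        "config": config.to_dict(),
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in sorted(paths.items())
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
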