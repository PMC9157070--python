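"""File formats and run configuration.

Formats are plain text: a tidy TSV dialect for mutation trajectories (one
row per mutation x timepoint), 2-column gene-length TSVs, gene-count TSVs
(gene, strain, regime, count), GFF3 + FASTA for gene annotation, and JSON
for configuration, fit reports, and ground truth.  Output files embed a
provenance comment (config hash and seed) as their first line; readers skip
``#`` comments.  Internal coordinates are 0-based half-open; conversion to
GFF3's 1-based inclusive convention happens only at the GFF3 boundary.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .parallelism import GeneCatalog, GeneMutationTable, effective_gene_lengths
from .synthetic import GroundTruth, SyntheticGenome
from .trajectories import TRAJECTORY_COLUMNS, TrajectoryMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_trajectories",
    "write_trajectories",
    "read_gene_lengths",
    "read_gene_annotation",
    "read_gene_counts",
    "write_gene_counts",
    "write_genome_fixture",
    "write_ground_truth",
    "provenance_line",
]

_STAGES = (
    "simulate",
    "synth",
    "trajstats",
    "fitmodel",
    "parallelism",
    "convergence",
    "report",
)


@dataclass
class RunConfig:
    """Per-stage parameters plus a provenance block echoed into outputs.

    ``stages`` maps a stage name (one of the pipeline subcommands) to its
    parameter dictionary; unknown stage names are rejected so typos fail
    loudly.
    """

    seed: int = 0
    stages: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown config stages: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {"seed", "stages"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(seed=raw.get("seed", 0), stages=raw.get("stages", {}))

    def stage(self, name: str) -> dict:
        return dict(self.stages.get(name, {}))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def provenance_line(config: RunConfig | None = None, seed: int | None = None) -> str:
    """Comment line embedding the config hash and seed (no timestamps, so
    reruns are byte-identical)."""
    h = config.config_hash if config is not None else "none"
    s = seed if seed is not None else (config.seed if config is not None else 0)
    return f"# seedbankevo config_hash={h} seed={s}"


# ---------------------------------------------------------------------------
# Trajectory TSV
# ---------------------------------------------------------------------------

def read_trajectories(path) -> TrajectoryMatrix:
    """Read and validate a trajectory TSV; errors cite the offending line."""
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for lineno, rec in enumerate(reader, start=1):
            if not rec or rec[0].startswith("#"):
                continue
            if header is None:
                header = rec
                if header != TRAJECTORY_COLUMNS:
                    raise ValueError(
                        f"{path}: malformed header on line {lineno}: expected "
                        f"{TRAJECTORY_COLUMNS}, got {header}"
                    )
                continue
            if len(rec) != len(TRAJECTORY_COLUMNS):
                raise ValueError(f"{path}: wrong field count on line {lineno}")
            row = dict(zip(TRAJECTORY_COLUMNS, rec))
            try:
                row["day"] = float(row["day"])
                row["generations"] = float(row["generations"])
                row["alt_count"] = int(row["alt_count"])
                row["depth"] = int(row["depth"])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric count on line {lineno}: {exc}"
                ) from None
            if row["alt_count"] > row["depth"]:
                raise ValueError(
                    f"{path}: alt_count exceeds depth on line {lineno}"
                )
            rows.append(row)
    if header is None:
        raise ValueError(f"{path}: empty file")
    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    traj = TrajectoryMatrix(df)
    logger.info(
        "read %d trajectory rows: %d populations, %d timepoints",
        len(df),
        df["population_id"].nunique(),
        df["day"].nunique(),
    )
    return traj


def write_trajectories(traj: TrajectoryMatrix, path, config: RunConfig | None = None) -> None:
    """Write the trajectory TSV dialect (UTF-8, Unix newlines)."""
    df = traj.data[TRAJECTORY_COLUMNS]
    with open(path, "w", newline="\n") as fh:
        fh.write(provenance_line(config) + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Gene catalogs
# ---------------------------------------------------------------------------

def read_gene_lengths(path, gene_sets: dict | None = None) -> GeneCatalog:
    """Gene catalog from a 2-column TSV (gene_id, effective length)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:2]) != ["gene_id", "length"]:
        raise ValueError(f"{path}: expected columns gene_id, length")
    series = df.set_index("gene_id")["length"]
    return GeneCatalog(series, gene_sets or {})


def read_gene_annotation(
    gff3_path,
    fasta_path,
    gene_sets: dict | None = None,
    codon_table_id: int = 11,
) -> GeneCatalog:
    """Gene catalog from GFF3 CDS features plus the genome FASTA.

    Coordinates follow the GFF3 standard (1-based, inclusive); minus-strand
    CDSs are reverse-complemented before codon site counting.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    sequences: dict = {}
    for feat in db.features_of_type("CDS"):
        gene = feat.attributes.get("ID", [feat.id])[0]
        if gene in sequences:
            raise ValueError(f"duplicate gene id {gene!r} in {gff3_path}")
        contig = contigs.get(feat.seqid)
        if contig is None:
            raise ValueError(f"contig {feat.seqid!r} missing from {fasta_path}")
        seq = contig[feat.start - 1: feat.end]  # GFF3 1-based inclusive
        if feat.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        sequences[gene] = seq
    return effective_gene_lengths(sequences, codon_table_id, gene_sets or {})


def read_gene_counts(path) -> dict:
    """Per-cohort gene mutation tables from a tidy counts TSV.

    Columns: gene_id, strain, regime, count.  Returns a dict keyed by
    ``"{strain}_{regime}"``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["gene_id", "strain", "regime", "count"]
    if list(df.columns) != required:
        raise ValueError(f"{path}: expected columns {required}")
    out = {}
    for (strain, regime), sub in df.groupby(["strain", "regime"], sort=True):
        out[f"{strain}_{regime}"] = GeneMutationTable(
            sub.set_index("gene_id")["count"]
        )
    return out


def write_gene_counts(tables: dict, path, config: RunConfig | None = None) -> None:
    """Write per-cohort gene counts as a tidy TSV (inverse of read_gene_counts)."""
    rows = []
    for cohort, table in sorted(tables.items()):
        strain, _, regime = cohort.rpartition("_")
        for gene, n in table.counts.items():
            rows.append((gene, strain, regime, int(n)))
    df = pd.DataFrame(rows, columns=["gene_id", "strain", "regime", "count"])
    with open(path, "w", newline="\n") as fh:
        fh.write(provenance_line(config) + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Genome fixtures and ground truth
# ---------------------------------------------------------------------------

def write_genome_fixture(genome: SyntheticGenome, fasta_path, gff3_path) -> None:
    """Write a synthetic genome as FASTA + GFF3 (CDS features)."""
    with open(fasta_path, "w", newline="\n") as fh:
        fh.write(">contig1\n")
        seq = genome.genome_sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    with open(gff3_path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for rec in genome.features.itertuples(index=False):
            fh.write(
                f"{rec.seqid}\tseedbankevo\tCDS\t{rec.start}\t{rec.end}\t.\t"
                f"{rec.strand}\t0\tID={rec.gene_id}\n"
            )


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Serialize ground truth (fates, enriched sets, generating spec) to JSON."""
    payload = {
        "fates": truth.fates.to_dict(orient="records"),
        "enriched_genes": {k: sorted(v) for k, v in truth.enriched_genes.items()},
        "spec": _spec_dict(truth.spec),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _spec_dict(spec) -> dict | None:
    if spec is None:
        return None
    d = asdict(spec)
    return d
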