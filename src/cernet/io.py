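"""File formats and core containers.

Expression matrices travel as TSV (feature rows, sample columns, log2
intensities), genomic annotation as GTF (1-based inclusive on disk,
0-based half-open in memory), sequences as FASTA, gene sets as GMT, and
transcription-factor motifs as JASPAR-style count matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SPECIES = ("lncRNA", "circRNA", "miRNA", "mRNA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_rna(seq: str) -> str:
    """Uppercase and map U to T so all sequence code works in DNA space."""
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """log2 expression for one RNA species over a shared sample set.

    ``values`` is a features x samples DataFrame; ``condition_of`` maps
    every sample id to its condition label.
    """

    species: str
    values: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples without condition: {missing}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate feature or sample ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s in self.values.columns if self.condition_of[s] == condition]
        if not out:
            raise KeyError(f"condition {condition!r} absent from matrix")
        return out

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.species,
            self.values[list(samples)],
            {s: self.condition_of[s] for s in samples},
        )


def write_expression(matrix: ExpressionMatrix, path: Path) -> None:
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_expression(path: Path, condition_of: Mapping[str, str], species: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id", float_precision="round_trip")
    df.index.name = None
    return ExpressionMatrix(species, df, dict(condition_of))


def write_sample_table(condition_of: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcondition\n")
        for s, c in condition_of.items():
            fh.write(f"{s}\t{c}\n")


def read_sample_table(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample_id"], df["condition"]))


# ---------------------------------------------------------------------------
# Genomic annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicFeature:
    """One locus in 0-based half-open coordinates.

    ``tss`` is the strand-dependent 5' end: ``start`` on +, ``end - 1``
    on -.  ``introns`` holds 0-based half-open intervals (empty for
    single-exon features).
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    introns: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.id}: bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def write_gtf(features: Sequence[GenomicFeature], path: Path, source: str = "cernet") -> None:
    """Emit transcript rows (plus exon rows for intron-bearing features).

    Internal 0-based half-open [start, end) becomes GTF 1-based inclusive
    [start + 1, end].
    """
    with open(path, "w") as fh:
        for f in features:
            attrs = f'gene_id "{f.id}"; transcript_id "{f.id}"; biotype "{f.biotype}";'
            fh.write(
                f"{f.chrom}\t{source}\ttranscript\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )
            if f.introns:
                # exons are the complement of the introns within the span
                edges = [f.start] + [x for iv in f.introns for x in iv] + [f.end]
                for s, e in zip(edges[::2], edges[1::2]):
                    fh.write(
                        f"{f.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{f.strand}\t.\t{attrs}\n"
                    )


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path: Path) -> list[GenomicFeature]:
    rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = line.rstrip(
                "\n"
            ).split("\t")
            a = _parse_attrs(attrs)
            fid = a["transcript_id"]
            start, end = int(start1) - 1, int(end1)
            if ftype == "transcript":
                rows[fid] = {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "biotype": a.get("biotype", "mRNA"),
                    "exons": [],
                }
                order.append(fid)
            elif ftype == "exon":
                rows[fid]["exons"].append((start, end))
    out = []
    for fid in order:
        r = rows[fid]
        introns: tuple[tuple[int, int], ...] = ()
        if len(r["exons"]) > 1:
            exons = sorted(r["exons"])
            introns = tuple((a[1], b[0]) for a, b in zip(exons, exons[1:]))
        out.append(
            GenomicFeature(fid, r["chrom"], r["start"], r["end"], r["strand"], r["biotype"], introns)
        )
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

NAMESPACES = ("BP", "CC", "MF", "pathway")


@dataclass
class GeneSetCollection:
    """Flat gene-set collection with a background universe.

    ``terms`` maps term id -> (name, namespace, member ids); namespaces
    follow GO classes plus a catch-all ``pathway`` class.
    """

    terms: dict[str, tuple[str, str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for tid, (_name, ns, members) in self.terms.items():
            if ns not in NAMESPACES:
                raise ValueError(f"{tid}: unknown namespace {ns!r}")
            if not members:
                raise ValueError(f"{tid}: empty term")


def write_gmt(collection: GeneSetCollection, path: Path) -> None:
    # description column carries "namespace|name" so the file round-trips
    with open(path, "w") as fh:
        for tid, (name, ns, members) in collection.terms.items():
            fh.write("\t".join([tid, f"{ns}|{name}"] + sorted(members)) + "\n")


def read_gmt(path: Path, background: frozenset[str] | None = None) -> GeneSetCollection:
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            tid, desc = parts[0], parts[1]
            ns, _, name = desc.partition("|")
            if ns not in NAMESPACES:
                ns, name = "pathway", desc
            members = frozenset(parts[2:])
            terms[tid] = (name, ns, members)
            seen |= members
    return GeneSetCollection(terms, background if background is not None else frozenset(seen))


# ---------------------------------------------------------------------------
# Motifs (JASPAR-style counts)
# ---------------------------------------------------------------------------

BASES = "ACGT"


@dataclass
class PWM:
    """Position weight matrix built from a 4 x L count matrix (rows ACGT).

    Probabilities are +1 pseudocount smoothed; background is uniform
    unless given.
    """

    motif_id: str
    counts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError(f"{self.motif_id}: counts must be 4 x L with L >= 4")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.motif_id}: negative counts")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probs(self) -> np.ndarray:
        smoothed = self.counts + 1.0
        return smoothed / smoothed.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


def write_jaspar(pwms: Sequence[PWM], path: Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
            for base, row in zip(BASES, pwm.counts):
                cells = " ".join(f"{int(round(v)):6d}" for v in row)
                fh.write(f"{base} [{cells} ]\n")


def read_jaspar(path: Path) -> list[PWM]:
    pwms: list[PWM] = []
    motif_id = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if motif_id is not None:
                    pwms.append(PWM(motif_id, np.array(rows)))
                motif_id = line[1:].split()[0]
                rows = []
            else:
                body = line.split("[", 1)[1].rsplit("]", 1)[0]
                rows.append([float(x) for x in body.split()])
    if motif_id is not None:
        pwms.append(PWM(motif_id, np.array(rows)))
    return pwms


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------

def write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: Path):
    with open(path) as fh:
        return json.load(fh)
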