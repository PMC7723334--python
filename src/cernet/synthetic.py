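"""Planted-truth study simulator.

Generates a complete fake three-condition profiling study — expression
matrices for four RNA species over a shared sample set, a synthetic
chromosome with annotated loci, sequences, gene sets and TF motifs —
with every downstream-discoverable structure planted on purpose and
recorded in a :class:`SyntheticTruth` oracle: differential features,
near-perfectly correlated pairs, ceRNA triplets with real seed sites,
cis lncRNA/gene neighbours of every positional class, and promoter
motifs.

The design mirrors a parental line plus two drug-resistant derivatives
(default conditions ``control``, ``resistantA``, ``resistantAB``) with
three biological replicates each.  Signals are additive on the log2
scale: planted DE features shift by ``de_log2_effect`` in the affected
condition(s); correlated sets share a condition-driven latent driver
plus small independent noise so their sample Pearson r approaches but
never equals 1; everything else is i.i.d. Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    PWM,
    BASES,
    ExpressionMatrix,
    GeneSetCollection,
    GenomicFeature,
    read_expression,
    read_fasta,
    read_gmt,
    read_gtf,
    read_jaspar,
    read_json,
    read_sample_table,
    revcomp,
    write_expression,
    write_fasta,
    write_gmt,
    write_gtf,
    write_jaspar,
    write_json,
    write_sample_table,
)

COMPARISON_NAMES = ("AvsCtrl", "BvsCtrl", "merged")

_ID_PREFIX = {"mRNA": "MRNA", "lncRNA": "LNC", "circRNA": "CIRC", "miRNA": "MIR"}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; the defaults are the study conditions.

    ``de_fraction`` is the proportion of non-reserved features per
    species given an independent planted shift of ``de_log2_effect``
    (log2 units) over replicate noise ``noise_sd``.  Correlated
    structures (pairs/triplets/cis) use a shared latent driver with
    per-sample jitter ``driver_jitter_sd`` and member noise
    ``pair_noise_sd``, keeping within-pair r ~ 0.9996 and cross-driver r
    well below the 0.99 edge threshold.
    """

    n_features: dict[str, int] = field(
        default_factory=lambda: {"lncRNA": 150, "circRNA": 150, "miRNA": 60, "mRNA": 300}
    )
    n_replicates: int = 3
    conditions: tuple[str, str, str] = ("control", "resistantA", "resistantAB")
    de_fraction: float = 0.1
    de_log2_effect: float = 2.0
    noise_sd: float = 0.25
    n_planted_pairs: int = 10
    n_planted_triplets: int = 8
    n_planted_cis_pairs: int = 10
    n_planted_motifs: int = 3
    n_motif_lncrnas: int = 4
    pair_noise_sd: float = 0.02
    driver_jitter_sd: float = 0.3
    utr_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must lie in [0, 1]")
        if len(self.conditions) != 3:
            raise ValueError("exactly three conditions required")
        for name in ("n_planted_pairs", "n_planted_triplets", "n_planted_cis_pairs",
                     "n_planted_motifs", "n_motif_lncrnas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("de_log2_effect", "noise_sd", "pair_noise_sd", "driver_jitter_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for sp, n in self.n_features.items():
            if n <= 0:
                raise ValueError(f"n_features[{sp}] must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{c}_{r + 1}" for c in self.conditions for r in range(self.n_replicates)]

    @property
    def condition_of(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_ids}


@dataclass
class SyntheticTruth:
    """Oracle of everything planted, keyed the way downstream stages report."""

    planted_de: dict[str, dict[str, set[tuple[str, str]]]]
    planted_pairs: set[tuple[str, str, str]]
    planted_triplets: set[tuple[str, str, str]]
    planted_cis: set[tuple[str, str, str]]
    planted_motifs: set[tuple[str, str, int]]

    def to_json_obj(self) -> dict:
        return {
            "planted_de": {
                comp: {sp: sorted(list(t) for t in items)
                       for sp, items in by_sp.items()}
                for comp, by_sp in self.planted_de.items()
            },
            "planted_pairs": sorted(list(t) for t in self.planted_pairs),
            "planted_triplets": sorted(list(t) for t in self.planted_triplets),
            "planted_cis": sorted(list(t) for t in self.planted_cis),
            "planted_motifs": sorted(list(t) for t in self.planted_motifs),
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "SyntheticTruth":
        return cls(
            planted_de={
                comp: {sp: {tuple(t) for t in items} for sp, items in by_sp.items()}
                for comp, by_sp in obj["planted_de"].items()
            },
            planted_pairs={tuple(t) for t in obj["planted_pairs"]},
            planted_triplets={tuple(t) for t in obj["planted_triplets"]},
            planted_cis={tuple(t) for t in obj["planted_cis"]},
            planted_motifs={(t[0], t[1], int(t[2])) for t in obj["planted_motifs"]},
        )


@dataclass
class DatasetBundle:
    expression: dict[str, ExpressionMatrix]
    features: list[GenomicFeature]
    chromosomes: dict[str, str]
    sequences: dict[str, dict[str, str]]  # miRNA / lncRNA / circRNA / utr3
    gene_sets: GeneSetCollection
    pwms: list[PWM]
    config: SimulationConfig


def _rng(config: SimulationConfig, offset: int) -> np.random.Generator:
    # fixed per-purpose offsets from one master seed
    return np.random.default_rng([int(config.seed) % (2 ** 31), offset])


def _ids(species: str, n: int) -> list[str]:
    return [f"{_ID_PREFIX[species]}{i + 1:04d}" for i in range(n)]


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASE_ARR[codes].tobytes().decode()


def generate_dataset(config: SimulationConfig) -> tuple[DatasetBundle, SyntheticTruth]:
    """Build the full bundle plus its ground truth; seed-deterministic."""
    n_pairs = config.n_planted_pairs
    n_trip = config.n_planted_triplets
    n_cis = config.n_planted_cis_pairs
    n_motif_lncs = config.n_planted_motifs * config.n_motif_lncrnas

    n_lnc_sponges = (n_trip + 1) // 2
    n_circ_sponges = n_trip // 2
    n_pair_circ = n_pairs // 2
    n_pair_mir = n_pairs // 2

    need = {
        "mRNA": n_trip + n_cis + n_pairs + n_pair_circ + n_pair_mir,
        "lncRNA": n_lnc_sponges + n_pairs + n_cis + n_motif_lncs,
        "circRNA": n_circ_sponges + n_pair_circ,
        "miRNA": n_trip + n_pair_mir,
    }
    for sp, k in need.items():
        if k > config.n_features[sp]:
            raise ValueError(
                f"n_features[{sp}]={config.n_features[sp]} too small for planted "
                f"structure (needs >= {k})"
            )

    mrna_ids = _ids("mRNA", config.n_features["mRNA"])
    lnc_ids = _ids("lncRNA", config.n_features["lncRNA"])
    circ_ids = _ids("circRNA", config.n_features["circRNA"])
    mir_ids = _ids("miRNA", config.n_features["miRNA"])

    # --- reserved id blocks -------------------------------------------------
    it = iter(mrna_ids)
    trip_mrnas = [next(it) for _ in range(n_trip)]
    cis_genes = [next(it) for _ in range(n_cis)]
    pair_mrnas_lnc = [next(it) for _ in range(n_pairs)]
    pair_mrnas_circ = [next(it) for _ in range(n_pair_circ)]
    pair_mrnas_mir = [next(it) for _ in range(n_pair_mir)]

    it = iter(lnc_ids)
    trip_lnc_sponges = [next(it) for _ in range(n_lnc_sponges)]
    pair_lncs = [next(it) for _ in range(n_pairs)]
    cis_lncs = [next(it) for _ in range(n_cis)]
    motif_lncs = [next(it) for _ in range(n_motif_lncs)]

    it = iter(circ_ids)
    trip_circ_sponges = [next(it) for _ in range(n_circ_sponges)]
    pair_circs = [next(it) for _ in range(n_pair_circ)]

    it = iter(mir_ids)
    trip_mirs = [next(it) for _ in range(n_trip)]
    pair_mirs = [next(it) for _ in range(n_pair_mir)]

    cis_categories = [
        ("sense", "antisense", "intronic", "divergent", "neighbor")[i % 5]
        for i in range(n_cis)
    ]

    # --- genome layout ------------------------------------------------------
    layout_rng = _rng(config, 1)
    features: dict[str, GenomicFeature] = {}
    cursor = 3000
    planted_plus = set(trip_mrnas) | set(trip_lnc_sponges) | set(pair_lncs) | set(motif_lncs)

    def gap() -> int:
        return int(layout_rng.integers(2500, 4000))

    cis_by_gene = dict(zip(cis_genes, zip(cis_lncs, cis_categories)))
    for gid in mrna_ids:
        glen = int(layout_rng.integers(1200, 2000))
        if gid in cis_by_gene:
            lnc_id, cat = cis_by_gene[gid]
            if cat == "divergent":
                lstart = cursor
                lnc = GenomicFeature(lnc_id, "chrS", lstart, lstart + 600, "-", "lncRNA")
                gstart = lstart + 600 + 400
                gene = GenomicFeature(gid, "chrS", gstart, gstart + glen, "+", "mRNA")
                cursor = gene.end + gap()
            else:
                gstart = cursor
                if cat == "intronic":
                    glen = max(glen, 1800)  # intron must fully contain the lncRNA
                    introns = ((gstart + 300, gstart + glen - 400),)
                    gene = GenomicFeature(gid, "chrS", gstart, gstart + glen, "+", "mRNA", introns)
                    lnc = GenomicFeature(lnc_id, "chrS", gstart + 400, gstart + 1000, "+", "lncRNA")
                else:
                    gene = GenomicFeature(gid, "chrS", gstart, gstart + glen, "+", "mRNA")
                    if cat == "sense":
                        lnc = GenomicFeature(lnc_id, "chrS", gstart + 200, gstart + 700, "+", "lncRNA")
                    elif cat == "antisense":
                        lnc = GenomicFeature(lnc_id, "chrS", gstart + 200, gstart + 700, "-", "lncRNA")
                    else:  # neighbor: tandem same-strand downstream
                        lstart = gene.end + 3000
                        lnc = GenomicFeature(lnc_id, "chrS", lstart, lstart + 600, "+", "lncRNA")
                cursor = max(gene.end, lnc.end) + gap()
            features[gid] = gene
            features[lnc_id] = lnc
        else:
            strand = "+" if gid in planted_plus else ("+", "-")[int(layout_rng.integers(2))]
            features[gid] = GenomicFeature(gid, "chrS", cursor, cursor + glen, strand, "mRNA")
            cursor = features[gid].end + gap()

    for lid in lnc_ids:
        if lid in features:  # cis lncRNAs already placed
            continue
        llen = int(layout_rng.integers(500, 900))
        strand = "+" if lid in planted_plus else ("+", "-")[int(layout_rng.integers(2))]
        features[lid] = GenomicFeature(lid, "chrS", cursor, cursor + llen, strand, "lncRNA")
        cursor = features[lid].end + gap()

    # circRNAs live inside host genes; planted sponges need a + strand host
    plus_hosts = [g for g in mrna_ids
                  if features[g].strand == "+" and g not in cis_by_gene and not features[g].introns]
    host_pick = _rng(config, 2)
    planted_circs = set(trip_circ_sponges) | set(pair_circs)
    for i, cid in enumerate(circ_ids):
        if cid in planted_circs:
            host = features[plus_hosts[i % len(plus_hosts)]]
        else:
            host = features[mrna_ids[int(host_pick.integers(len(mrna_ids)))]]
        clen = int(host_pick.integers(300, 450))
        span = host.end - config.utr_length - 100 - clen - (host.start + 50)
        off = int(host_pick.integers(max(1, span))) if span > 0 else 0
        start = host.start + 50 + off
        features[cid] = GenomicFeature(cid, "chrS", start, start + clen, host.strand, "circRNA")

    for mid in mir_ids:
        features[mid] = GenomicFeature(mid, "chrS", cursor, cursor + 22, "+", "miRNA")
        cursor = features[mid].end + 500

    chrom_len = cursor + 3000
    chrom = _random_bases(_rng(config, 3), chrom_len)

    # --- plant sequences ----------------------------------------------------
    site_rng = _rng(config, 4)

    def write_seq(pos: int, seq: str) -> None:
        chrom[pos : pos + len(seq)] = [BASES.index(c) for c in seq]

    # alternate lncRNA and circRNA sponges so both species are exercised
    sponges = [
        trip_lnc_sponges[i // 2] if i % 2 == 0 else trip_circ_sponges[i // 2]
        for i in range(n_trip)
    ]
    triplets = list(zip(sponges, trip_mirs, trip_mrnas))
    for sponge_id, mir_id, mrna_id in triplets:
        mir = features[mir_id]
        mir_seq = _to_str(chrom[mir.start : mir.end])
        site8 = revcomp(mir_seq[1:8]) + "A"
        gene = features[mrna_id]
        utr_start = gene.end - config.utr_length
        write_seq(utr_start + 50 + int(site_rng.integers(0, config.utr_length - 70)), site8)
        sponge = features[sponge_id]
        span = (sponge.end - sponge.start) - 60
        write_seq(sponge.start + 30 + int(site_rng.integers(0, span)), site8)

    # trans-similarity: each planted lncRNA-mRNA pair shares a 40-nt exact
    # segment between the lncRNA body and the partner mRNA 3'UTR, so
    # alignment-based trans prediction has true positives among the
    # co-expressed pairs
    for lnc_id, mrna_id in zip(pair_lncs, pair_mrnas_lnc):
        gene = features[mrna_id]
        if gene.strand == "+":
            segment = _to_str(chrom[gene.end - config.utr_length : gene.end - config.utr_length + 40])
        else:
            segment = revcomp(_to_str(chrom[gene.start + config.utr_length - 40 : gene.start + config.utr_length]))
        write_seq(features[lnc_id].start + 200, segment)

    # motifs: strong-consensus PWMs planted upstream of chosen lncRNAs
    motif_rng = _rng(config, 5)
    pwms: list[PWM] = []
    planted_motifs: set[tuple[str, str, int]] = set()
    lnc_iter = iter(motif_lncs)
    for m in range(config.n_planted_motifs):
        length = int(motif_rng.integers(9, 13))
        consensus_codes = _random_bases(motif_rng, length)
        counts = np.full((4, length), 5.0)
        counts[consensus_codes, np.arange(length)] = 85.0
        motif_id = f"TF{m + 1:02d}"
        pwm = PWM(motif_id, counts)
        pwms.append(pwm)
        consensus = _to_str(consensus_codes)
        for _ in range(config.n_motif_lncrnas):
            lnc = features[next(lnc_iter)]
            offset = int(motif_rng.integers(300, 1200))  # window offset, upstream part
            write_seq(lnc.tss - 2000 + offset, consensus)
            planted_motifs.add((lnc.id, motif_id, offset))

    chrom_str = _to_str(chrom)

    def feature_seq(f: GenomicFeature) -> str:
        s = chrom_str[f.start : f.end]
        return s if f.strand == "+" else revcomp(s)

    def utr_seq(f: GenomicFeature) -> str:
        if f.strand == "+":
            return chrom_str[f.end - config.utr_length : f.end]
        return revcomp(chrom_str[f.start : f.start + config.utr_length])

    sequences = {
        "miRNA": {i: feature_seq(features[i]) for i in mir_ids},
        "lncRNA": {i: feature_seq(features[i]) for i in lnc_ids},
        "circRNA": {i: feature_seq(features[i]) for i in circ_ids},
        "utr3": {i: utr_seq(features[i]) for i in mrna_ids},
    }

    # --- expression ---------------------------------------------------------
    samples = config.sample_ids
    cond = config.condition_of
    n_samples = len(samples)
    cond_a, cond_b = config.conditions[1], config.conditions[2]
    mask_a = np.array([cond[s] == cond_a for s in samples], dtype=float)
    mask_b = np.array([cond[s] == cond_b for s in samples], dtype=float)

    planted_de: dict[str, dict[str, set[tuple[str, str]]]] = {
        comp: {sp: set() for sp in _ID_PREFIX} for comp in COMPARISON_NAMES
    }
    all_ids = {"mRNA": mrna_ids, "lncRNA": lnc_ids, "circRNA": circ_ids, "miRNA": mir_ids}
    reserved = {
        "mRNA": trip_mrnas + cis_genes + pair_mrnas_lnc + pair_mrnas_circ + pair_mrnas_mir,
        "lncRNA": trip_lnc_sponges + pair_lncs + cis_lncs + motif_lncs,
        "circRNA": trip_circ_sponges + pair_circs,
        "miRNA": trip_mirs + pair_mirs,
    }
    values: dict[str, pd.DataFrame] = {}
    for offs, sp in enumerate(_ID_PREFIX):
        rng = _rng(config, 10 + offs)
        ids = all_ids[sp]
        baseline = rng.uniform(6.0, 12.0, size=len(ids))
        mat = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(len(ids), n_samples))
        free = [i for i in ids if i not in set(reserved[sp])]
        n_de = int(round(config.de_fraction * len(free)))
        chosen = list(rng.choice(len(free), size=n_de, replace=False)) if n_de else []
        ix = {fid: k for k, fid in enumerate(ids)}
        for c in chosen:
            fid = free[int(c)]
            cat = ("both", "A", "B")[int(rng.choice(3, p=[0.5, 0.25, 0.25]))]
            direction = 1 if rng.integers(2) else -1
            word = "up" if direction > 0 else "down"
            shift = direction * config.de_log2_effect
            if cat in ("both", "A"):
                mat[ix[fid]] += shift * mask_a
                planted_de["AvsCtrl"][sp].add((fid, word))
            if cat in ("both", "B"):
                mat[ix[fid]] += shift * mask_b
                planted_de["BvsCtrl"][sp].add((fid, word))
            if cat == "both":
                planted_de["merged"][sp].add((fid, word))
        if sp == "lncRNA":
            # motif-carrying lncRNAs are made DE in both comparisons so the
            # promoter/TF stage (which analyses DE lncRNAs) sees them
            for j, fid in enumerate(motif_lncs):
                direction = 1 if j % 2 == 0 else -1
                word = "up" if direction > 0 else "down"
                mat[ix[fid]] += direction * config.de_log2_effect * (mask_a + mask_b)
                for comp in COMPARISON_NAMES:
                    planted_de[comp][sp].add((fid, word))
        values[sp] = pd.DataFrame(mat, index=ids, columns=samples)

    driver_rng = _rng(config, 20)

    def make_driver(direction: int) -> np.ndarray:
        # amplitude varies per driver (1.1-1.5x the base effect) so planted
        # signals clear the DE gates robustly while distinct drivers stay
        # decorrelated through the per-sample jitter
        amp = config.de_log2_effect * driver_rng.uniform(1.1, 1.5)
        pattern = direction * amp * (mask_a + mask_b)
        return pattern + driver_rng.normal(0.0, config.driver_jitter_sd, size=n_samples)

    def plant(sp: str, fid: str, profile: np.ndarray, word: str) -> None:
        noise = driver_rng.normal(0.0, config.pair_noise_sd, size=n_samples)
        base = values[sp].loc[fid].to_numpy().mean()  # keep a feature-specific level
        values[sp].loc[fid] = round(base, 3) + profile + noise
        for comp in COMPARISON_NAMES:
            planted_de[comp][sp].add((fid, word))

    planted_pairs: set[tuple[str, str, str]] = set()
    for i, (a, b) in enumerate(zip(pair_lncs, pair_mrnas_lnc)):
        d = make_driver(1 if i % 2 == 0 else -1)
        word = "up" if i % 2 == 0 else "down"
        plant("lncRNA", a, d, word)
        plant("mRNA", b, d, word)
        planted_pairs.add((a, b, "positive"))
    for i, (a, b) in enumerate(zip(pair_circs, pair_mrnas_circ)):
        d = make_driver(1 if i % 2 == 0 else -1)
        word = "up" if i % 2 == 0 else "down"
        plant("circRNA", a, d, word)
        plant("mRNA", b, d, word)
        planted_pairs.add((a, b, "positive"))
    for a, b in zip(pair_mirs, pair_mrnas_mir):
        d = make_driver(1)
        plant("miRNA", a, -d, "down")
        plant("mRNA", b, d, "up")
        planted_pairs.add((a, b, "negative"))

    planted_triplets: set[tuple[str, str, str]] = set()
    for sponge_id, mir_id, mrna_id in triplets:
        d = make_driver(1)  # sponge and mRNA up, miRNA down in resistant lines
        sp_species = "lncRNA" if sponge_id.startswith("LNC") else "circRNA"
        plant(sp_species, sponge_id, d, "up")
        plant("mRNA", mrna_id, d, "up")
        plant("miRNA", mir_id, -d, "down")
        planted_triplets.add((sponge_id, mir_id, mrna_id))

    planted_cis: set[tuple[str, str, str]] = set()
    for (gene_id, (lnc_id, cat)) in cis_by_gene.items():
        d = make_driver(1)
        plant("lncRNA", lnc_id, d, "up")
        plant("mRNA", gene_id, d, "up")
        planted_cis.add((lnc_id, gene_id, cat))

    expression = {
        sp: ExpressionMatrix(sp, values[sp], dict(cond)) for sp in _ID_PREFIX
    }

    # --- gene sets ----------------------------------------------------------
    gs_rng = _rng(config, 30)
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    namespaces = ("BP", "CC", "MF", "pathway")
    for t in range(24):
        size = int(gs_rng.integers(5, 31))
        members = frozenset(
            mrna_ids[int(i)] for i in gs_rng.choice(len(mrna_ids), size=size, replace=False)
        )
        tid = f"TERM{t + 1:04d}"
        terms[tid] = (f"synthetic term {t + 1}", namespaces[t % 4], members)
    # two terms loaded with planted-DE mRNAs so enrichment has real signal
    de_mrnas = sorted({fid for fid, _ in planted_de["merged"]["mRNA"]})
    if len(de_mrnas) >= 5:
        picked = [de_mrnas[int(i)] for i in
                  gs_rng.choice(len(de_mrnas), size=min(15, len(de_mrnas)), replace=False)]
        extra = [mrna_ids[int(i)] for i in gs_rng.choice(len(mrna_ids), size=5, replace=False)]
        terms["TERM9001"] = ("planted enriched process", "BP", frozenset(picked + extra[:2]))
        terms["TERM9002"] = ("planted enriched pathway", "pathway", frozenset(picked[::2] + extra[2:]))
    gene_sets = GeneSetCollection(terms, frozenset(mrna_ids))

    ordered = [features[i] for i in mrna_ids + lnc_ids + circ_ids + mir_ids]
    bundle = DatasetBundle(
        expression=expression,
        features=ordered,
        chromosomes={"chrS": chrom_str},
        sequences=sequences,
        gene_sets=gene_sets,
        pwms=pwms,
        config=config,
    )
    truth = SyntheticTruth(
        planted_de=planted_de,
        planted_pairs=planted_pairs,
        planted_triplets=planted_triplets,
        planted_cis=planted_cis,
        planted_motifs=planted_motifs,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Disk round-trip
# ---------------------------------------------------------------------------

def write_dataset(bundle: DatasetBundle, truth: SyntheticTruth, out_dir: Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, matrix in bundle.expression.items():
        write_expression(matrix, out / f"expression_{sp}.tsv")
    write_sample_table(next(iter(bundle.expression.values())).condition_of, out / "samples.tsv")
    write_gtf(bundle.features, out / "annotation.gtf")
    write_fasta(bundle.chromosomes, out / "genome.fa")
    write_fasta(bundle.sequences["miRNA"], out / "mirna.fa")
    write_fasta(bundle.sequences["lncRNA"], out / "lncrna.fa")
    write_fasta(bundle.sequences["circRNA"], out / "circrna.fa")
    write_fasta(bundle.sequences["utr3"], out / "utr3.fa")
    write_gmt(bundle.gene_sets, out / "gene_sets.gmt")
    (out / "background.txt").write_text(
        "\n".join(sorted(bundle.gene_sets.background)) + "\n"
    )
    write_jaspar(bundle.pwms, out / "motifs.jaspar")
    cfg = asdict(bundle.config)
    cfg["conditions"] = list(cfg["conditions"])
    write_json(cfg, out / "config.json")
    write_json(truth.to_json_obj(), out / "truth.json")


def read_dataset(in_dir: Path) -> tuple[DatasetBundle, SyntheticTruth]:
    src = Path(in_dir)
    cfg_obj = read_json(src / "config.json")
    cfg_obj["conditions"] = tuple(cfg_obj["conditions"])
    config = SimulationConfig(**cfg_obj)
    condition_of = read_sample_table(src / "samples.tsv")
    expression = {
        sp: read_expression(src / f"expression_{sp}.tsv", condition_of, sp)
        for sp in _ID_PREFIX
    }
    background = frozenset(
        line for line in (src / "background.txt").read_text().splitlines() if line
    )
    bundle = DatasetBundle(
        expression=expression,
        features=read_gtf(src / "annotation.gtf"),
        chromosomes=read_fasta(src / "genome.fa"),
        sequences={
            "miRNA": read_fasta(src / "mirna.fa"),
            "lncRNA": read_fasta(src / "lncrna.fa"),
            "circRNA": read_fasta(src / "circrna.fa"),
            "utr3": read_fasta(src / "utr3.fa"),
        },
        gene_sets=read_gmt(src / "gene_sets.gmt", background),
        pwms=read_jaspar(src / "motifs.jaspar"),
        config=config,
    )
    truth = SyntheticTruth.from_json_obj(read_json(src / "truth.json"))
    return bundle, truth
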