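"""Canonical-seed miRNA target-site prediction.

A transparent seed-match scanner classifies sites into the canonical
classes (8mer > 7mer-m8 > 7mer-A1 > 6mer), defined by Watson-Crick
complementarity of miRNA seed positions 2-8 (5'->3') plus an optional
adenosine opposite miRNA position 1.  It replaces alignment/energy-based
tools with an exactly specified, verifiable rule; no thermodynamics or
conservation scoring is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import normalize_rna, revcomp

SITE_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
CLASS_RANK = {c: i for i, c in enumerate(SITE_CLASSES)}
CLASS_SCORE = {"8mer": 4.0, "7mer-m8": 3.0, "7mer-A1": 2.0, "6mer": 1.0}

_VALID = set("ACGT")


def _check_alphabet(seq: str, what: str) -> str:
    seq = normalize_rna(seq)
    if not seq or set(seq) - _VALID:
        raise ValueError(f"invalid {what} alphabet (ACGU/ACGT only)")
    return seq


def seed_of(mirna_sequence: str) -> str:
    """The 7-nt seed: miRNA positions 2-8 (1-based, 5'->3'), U -> T."""
    seq = _check_alphabet(mirna_sequence, "miRNA")
    if len(seq) < 8:
        raise ValueError("miRNA must be >= 8 nt")
    return seq[1:8]


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int       # 0-based offset of the matched window in the target
    end: int         # half-open
    site_class: str
    score: float


def find_seed_sites(
    mirna_sequence: str,
    target_sequence: str,
    mirna_id: str = "miRNA",
    transcript_id: str = "target",
) -> list[TargetSite]:
    """Scan a target 5'->3' for canonical seed-match sites.

    Patterns (target sense strand, 5'->3'):
      8mer     revcomp(seed 2-8) + A     (A opposite miRNA position 1)
      7mer-m8  revcomp(seed 2-8)
      7mer-A1  revcomp(seed 2-7) + A
      6mer     revcomp(seed 2-7)
    A window matching several patterns is reported once at its highest
    class; the site score is the class weight.
    """
    target = _check_alphabet(target_sequence, "target")
    seed7 = seed_of(mirna_sequence)
    match7 = revcomp(seed7)          # pairs seed 2-8
    match6 = revcomp(seed7[:6])      # pairs seed 2-7; 3' end aligns with match7

    sites: dict[int, tuple[str, int]] = {}  # 6mer start -> (class, window start)

    def record(core_start: int, site_class: str, win_start: int) -> None:
        prev = sites.get(core_start)
        if prev is None or CLASS_RANK[site_class] > CLASS_RANK[prev[0]]:
            sites[core_start] = (site_class, win_start)

    # 7mer-m8 core occurrences (revcomp(2-8)); its 3' 6 nt are the 6mer core
    for i in range(len(target) - 6):
        if target[i : i + 7] == match7:
            core = i + 1
            if core + 6 < len(target) and target[core + 6] == "A":
                record(core, "8mer", i)
            else:
                record(core, "7mer-m8", i)
    for i in range(len(target) - 5):
        if target[i : i + 6] == match6:
            if i + 6 < len(target) and target[i + 6] == "A":
                record(i, "7mer-A1", i)
            else:
                record(i, "6mer", i)

    out = []
    for _core, (site_class, start) in sorted(sites.items()):
        length = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[site_class]
        out.append(
            TargetSite(mirna_id, transcript_id, start, start + length,
                       site_class, CLASS_SCORE[site_class])
        )
    return out


def predict_targets(
    mirna_seqs: dict[str, str],
    transcript_seqs: dict[str, str],
    min_class: str = "7mer-A1",
    pairs=None,
) -> dict[tuple[str, str], list[TargetSite]]:
    """(miRNA, transcript) pairs with >= 1 site at or above ``min_class``.

    ``pairs`` optionally restricts the scan to given (mirna_id,
    transcript_id) candidates; results are independent of input order.
    """
    if min_class not in CLASS_RANK:
        raise ValueError(f"unknown site class {min_class!r}")
    min_rank = CLASS_RANK[min_class]
    if pairs is None:
        pairs = [(m, t) for m in sorted(mirna_seqs) for t in sorted(transcript_seqs)]
    out: dict[tuple[str, str], list[TargetSite]] = {}
    for mirna_id, transcript_id in sorted(set(pairs)):
        if mirna_id not in mirna_seqs:
            raise KeyError(f"miRNA {mirna_id!r} missing from sequence store")
        if transcript_id not in transcript_seqs:
            raise KeyError(f"transcript {transcript_id!r} missing from sequence store")
        sites = find_seed_sites(
            mirna_seqs[mirna_id], transcript_seqs[transcript_id], mirna_id, transcript_id
        )
        kept = [s for s in sites if CLASS_RANK[s.site_class] >= min_rank]
        if kept:
            out[(mirna_id, transcript_id)] = kept
    return out


def sites_to_frame(site_map: dict[tuple[str, str], list[TargetSite]]) -> pd.DataFrame:
    rows = [
        (s.mirna_id, s.transcript_id, s.start, s.end, s.site_class, s.score)
        for sites in site_map.values()
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["mirna_id", "transcript_id", "start", "end", "site_class", "score"]
    )
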