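"""Sign-constrained ceRNA triplet assembly.

A (sponge, miRNA, mRNA) triplet — sponge a lncRNA or circRNA — is
emitted when (i) the sponge and mRNA share a positive co-expression
edge, (ii) the miRNA has predicted seed sites in both the sponge and the
mRNA, and (iii) the miRNA's expression correlates negatively with both,
passing the same |r|/alpha gates as ordinary edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .coexpression import CorrelationRule, correlation_matrix
from .io import ExpressionMatrix
from .targeting import TargetSite

TRIPLET_COLUMNS = [
    "sponge_id", "sponge_species", "mirna_id", "mrna_id",
    "sponge_mrna_r", "mirna_sponge_r", "mirna_mrna_r",
    "n_sites_sponge", "n_sites_mrna",
]


@dataclass(frozen=True)
class CeRNATriplet:
    sponge_id: str
    sponge_species: str
    mirna_id: str
    mrna_id: str
    sponge_mrna_r: float
    mirna_sponge_r: float
    mirna_mrna_r: float
    sponge_sites: tuple[TargetSite, ...]
    mrna_sites: tuple[TargetSite, ...]

    def __post_init__(self) -> None:
        if not (self.sponge_mrna_r > 0 and self.mirna_sponge_r < 0 and self.mirna_mrna_r < 0):
            raise ValueError("triplet violates the sign constraints")
        if not (self.sponge_sites and self.mrna_sites):
            raise ValueError("triplet requires sites in both sponge and mRNA")


def assemble_triplets(
    sponge_mrna_edges: pd.DataFrame,
    mirna_expr: ExpressionMatrix,
    sponge_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    target_map: dict[tuple[str, str], list[TargetSite]],
    mirna_ids=None,
    rule: CorrelationRule = CorrelationRule(min_abs_r=0.99, alpha=0.05, required_sign="negative"),
    samples=None,
) -> list[CeRNATriplet]:
    """Combine positive sponge-mRNA edges with shared-miRNA evidence.

    ``target_map`` comes from :func:`cernet.targeting.predict_targets`
    and must cover miRNA pairs with both sponges and mRNAs.
    ``mirna_ids`` restricts the miRNA universe (e.g. to DE miRNAs);
    default is every miRNA in the expression matrix.  Output order is
    lexical in (sponge, miRNA, mRNA).
    """
    if mirna_ids is None:
        mirna_ids = mirna_expr.feature_ids
    mirna_ids = sorted(set(mirna_ids))
    known = set(mirna_expr.feature_ids)
    unknown = set(mirna_ids) - known
    if unknown:
        raise KeyError(f"unknown miRNA ids: {sorted(unknown)[:5]}")
    edges = sponge_mrna_edges[sponge_mrna_edges["sign"] == "positive"]
    if edges.empty or not mirna_ids:
        return []

    if samples is None:
        samples = [s for s in mirna_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    sponges = sorted(set(edges["node_a"]))
    mrnas = sorted(set(edges["node_b"]))
    r_ms, p_ms = correlation_matrix(mirna_expr, sponge_expr, mirna_ids, sponges, samples)
    r_mm, p_mm = correlation_matrix(mirna_expr, mrna_expr, mirna_ids, mrnas, samples)
    sponge_ix = {s: i for i, s in enumerate(sponges)}
    mrna_ix = {m: i for i, m in enumerate(mrnas)}

    def leg_ok(r: float, p: float) -> bool:
        return r < 0 and abs(r) >= rule.min_abs_r and p < rule.alpha

    out = []
    for _, edge in edges.iterrows():
        sponge, mrna = edge["node_a"], edge["node_b"]
        for mi, mirna in enumerate(mirna_ids):
            sponge_sites = target_map.get((mirna, sponge))
            mrna_sites = target_map.get((mirna, mrna))
            if not sponge_sites or not mrna_sites:
                continue
            si, ti = sponge_ix[sponge], mrna_ix[mrna]
            if not (leg_ok(r_ms[mi, si], p_ms[mi, si]) and leg_ok(r_mm[mi, ti], p_mm[mi, ti])):
                continue
            out.append(
                CeRNATriplet(
                    sponge_id=sponge,
                    sponge_species=edge["species_a"],
                    mirna_id=mirna,
                    mrna_id=mrna,
                    sponge_mrna_r=float(edge["r"]),
                    mirna_sponge_r=float(r_ms[mi, si]),
                    mirna_mrna_r=float(r_mm[mi, ti]),
                    sponge_sites=tuple(sponge_sites),
                    mrna_sites=tuple(mrna_sites),
                )
            )
    return sorted(out, key=lambda t: (t.sponge_id, t.mirna_id, t.mrna_id))


def triplets_to_frame(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    rows = [
        (t.sponge_id, t.sponge_species, t.mirna_id, t.mrna_id,
         t.sponge_mrna_r, t.mirna_sponge_r, t.mirna_mrna_r,
         len(t.sponge_sites), len(t.mrna_sites))
        for t in triplets
    ]
    return pd.DataFrame(rows, columns=TRIPLET_COLUMNS)


def triplet_network_summary(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    """Per-miRNA degree: number of distinct sponge/mRNA partners.

    Ranking is by descending degree with lexical tie-break.
    """
    partners: dict[str, set[str]] = {}
    for t in triplets:
        partners.setdefault(t.mirna_id, set()).update((t.sponge_id, t.mrna_id))
    rows = sorted(
        ((m, len(p)) for m, p in partners.items()), key=lambda kv: (-kv[1], kv[0])
    )
    return pd.DataFrame(rows, columns=["mirna_id", "degree"])


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_network(
    triplets: list[CeRNATriplet],
    path: Path,
    fmt: str = "tsv",
    node_attrs: dict[str, dict] | None = None,
) -> None:
    """Write a triplet network as tsv, sif, or graphml.

    ``node_attrs`` may carry per-node metadata (species, DE direction)
    for the graphml export.  The tsv export round-trips through
    :func:`read_triplet_tsv`.
    """
    if fmt == "tsv":
        triplets_to_frame(triplets).to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for t in triplets:
                fh.write(f"{t.sponge_id}\tsponges\t{t.mirna_id}\n")
                fh.write(f"{t.mirna_id}\ttargets\t{t.mrna_id}\n")
                fh.write(f"{t.sponge_id}\tcoexpressed\t{t.mrna_id}\n")
    elif fmt == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        for t in triplets:
            for node, species in (
                (t.sponge_id, t.sponge_species),
                (t.mirna_id, "miRNA"),
                (t.mrna_id, "mRNA"),
            ):
                attrs = {"species": species}
                if node_attrs and node in node_attrs:
                    attrs.update({k: escape(str(v)) for k, v in node_attrs[node].items()})
                g.add_node(node, **attrs)
            g.add_edge(t.sponge_id, t.mirna_id, relation="sponges", r=t.mirna_sponge_r)
            g.add_edge(t.mirna_id, t.mrna_id, relation="targets", r=t.mirna_mrna_r)
            g.add_edge(t.sponge_id, t.mrna_id, relation="coexpressed", r=t.sponge_mrna_r)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_triplet_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def verify_sign_constraints(
    triplets: list[CeRNATriplet],
    mirna_expr: ExpressionMatrix,
    sponge_exprs: dict[str, ExpressionMatrix],
    mrna_expr: ExpressionMatrix,
    samples=None,
) -> bool:
    """Recompute the three correlations of every triplet from expression
    and check sponge-mRNA > 0, miRNA-sponge < 0, miRNA-mRNA < 0."""
    from .coexpression import pearson_with_p

    if samples is None:
        samples = mirna_expr.sample_ids
    for t in triplets:
        sponge_expr = sponge_exprs[t.sponge_species]
        sp = sponge_expr.values.loc[t.sponge_id, list(samples)].to_numpy(dtype=float)
        mi = mirna_expr.values.loc[t.mirna_id, list(samples)].to_numpy(dtype=float)
        mr = mrna_expr.values.loc[t.mrna_id, list(samples)].to_numpy(dtype=float)
        r_sm, _ = pearson_with_p(sp, mr)
        r_ms, _ = pearson_with_p(mi, sp)
        r_mm, _ = pearson_with_p(mi, mr)
        if not (r_sm > 0 and r_ms < 0 and r_mm < 0):
            return False
        if not np.isclose(r_sm, t.sponge_mrna_r) or not np.isclose(r_ms, t.mirna_sponge_r):
            return False
    return True
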