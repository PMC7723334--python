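"""End-to-end orchestration.

``run_pipeline`` executes simulate -> normalize/DE -> co-expression ->
seed targeting -> ceRNA assembly -> cis/trans/TF prediction ->
enrichment, writing one TSV per stage output plus a JSON manifest
(parameters, row counts, content hashes).  Reruns with an unchanged
configuration skip stages whose recorded input hashes still match.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cerna, coexpression, de, enrichment, preprocess, regulation, targeting
from .coexpression import CorrelationRule
from .de import ThresholdPolicy
from .io import SPECIES, write_json
from .synthetic import (
    COMPARISON_NAMES,
    DatasetBundle,
    SimulationConfig,
    generate_dataset,
    read_dataset,
    write_dataset,
)

logger = logging.getLogger("cernet.pipeline")

STAGES = ("simulate", "de", "coexpress", "targets", "cerna", "cis", "trans", "tf", "enrich")


class ValidationError(ValueError):
    """Raised when a pipeline configuration or input bundle is invalid."""


@dataclass
class PipelineConfig:
    outdir: Path
    simulate: SimulationConfig | None = None
    input_dir: Path | None = None
    thresholds: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    correlation: CorrelationRule = field(default_factory=CorrelationRule)
    normalize: str = "none"  # input matrices are assumed pre-normalized log2
    min_class: str = "7mer-A1"
    cis_window: int = 10_000
    cis_min_r: float = 0.99
    cis_holm_alpha: float = 0.5
    trans_min_len: int = 20
    trans_min_identity: float = 0.9
    pwm_threshold: float = 0.8
    min_term_size: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulate is None and self.input_dir is None:
            raise ValidationError("config needs either a simulate block or an input_dir")
        if not (0.0 <= self.correlation.min_abs_r <= 1.0):
            raise ValidationError("correlation.min_abs_r outside [0, 1]")
        if self.normalize not in ("none", "quantile"):
            raise ValidationError("normalize must be 'none' or 'quantile'")
        if self.min_class not in targeting.CLASS_RANK:
            raise ValidationError(f"unknown targeting min_class {self.min_class!r}")
        if self.cis_window <= 0:
            raise ValidationError("cis window must be positive")
        if not (0.0 < self.pwm_threshold <= 1.0):
            raise ValidationError("pwm_threshold must lie in (0, 1]")


def load_config(path: Path) -> PipelineConfig:
    """Parse a YAML pipeline configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        sim = None
        if "simulate" in raw:
            blk = dict(raw["simulate"])
            if "conditions" in blk:
                blk["conditions"] = tuple(blk["conditions"])
            sim = SimulationConfig(**blk)
        thr = ThresholdPolicy(**raw.get("thresholds", {}))
        corr = CorrelationRule(**raw.get("correlation", {}))
        known = {
            "normalize", "min_class", "cis_window", "cis_min_r", "cis_holm_alpha",
            "trans_min_len", "trans_min_identity", "pwm_threshold",
            "min_term_size", "seed", "log_level",
        }
        extra = {k: v for k, v in raw.items() if k in known}
        return PipelineConfig(
            outdir=Path(raw["outdir"]),
            simulate=sim,
            input_dir=Path(raw["input_dir"]) if "input_dir" in raw else None,
            thresholds=thr,
            correlation=corr,
            **extra,
        )
    except (ValueError, KeyError, TypeError) as exc:
        raise ValidationError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(bundle: DatasetBundle) -> list[dict]:
    """Machine-readable issue list: id cross-references, duplicates,
    coordinate sanity, sequence alphabets."""
    issues: list[dict] = []
    annotated = {f.id for f in bundle.features}
    seq_store = {
        "lncRNA": bundle.sequences["lncRNA"],
        "circRNA": bundle.sequences["circRNA"],
        "miRNA": bundle.sequences["miRNA"],
        "mRNA": bundle.sequences["utr3"],
    }
    for sp in SPECIES:
        matrix = bundle.expression[sp]
        dup = matrix.values.index[matrix.values.index.duplicated()].tolist()
        for fid in dup:
            issues.append({"kind": "duplicate_id", "species": sp, "id": fid})
        for fid in matrix.feature_ids:
            if fid not in annotated:
                issues.append({"kind": "missing_annotation", "species": sp, "id": fid})
            if fid not in seq_store[sp]:
                issues.append({"kind": "missing_sequence", "species": sp, "id": fid})
    for f in bundle.features:
        if f.chrom not in bundle.chromosomes:
            issues.append({"kind": "unknown_chromosome", "id": f.id, "chrom": f.chrom})
        elif f.end > len(bundle.chromosomes[f.chrom]):
            issues.append({"kind": "out_of_bounds", "id": f.id})
    valid = set("ACGT")
    for group, seqs in bundle.sequences.items():
        for fid, seq in seqs.items():
            if set(seq) - valid:
                issues.append({"kind": "invalid_alphabet", "group": group, "id": fid})
    return issues


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def comparison_samples(bundle: DatasetBundle, comparison: str) -> list[str]:
    """Samples entering a comparison's correlations: the two conditions of
    the comparison, or every sample for the merged group."""
    conditions = bundle.config.conditions
    matrix = bundle.expression["mRNA"]
    if comparison == "AvsCtrl":
        keep = {conditions[0], conditions[1]}
    elif comparison == "BvsCtrl":
        keep = {conditions[0], conditions[2]}
    else:
        keep = set(conditions)
    return [s for s in matrix.sample_ids if matrix.condition_of[s] in keep]


def stage_de(
    bundle: DatasetBundle, policy: ThresholdPolicy, normalize: str = "none"
) -> dict[str, pd.DataFrame]:
    """Optionally normalize each species, then call DE for the three groups.

    ``normalize='quantile'`` applies quantile normalization first; the
    default trusts the input matrices to be on a common log2 scale
    already (quantile normalization needs a large feature set with a
    small differential fraction to be distribution-preserving).
    """
    conditions = bundle.config.conditions
    out: dict[str, pd.DataFrame] = {}
    if normalize == "quantile":
        normalized = {sp: preprocess.quantile_normalize(m) for sp, m in bundle.expression.items()}
    else:
        normalized = dict(bundle.expression)
    for sp, matrix in normalized.items():
        calls_a = de.call_de(
            de.differential_test(matrix, conditions[0], conditions[1]), policy, sp, "AvsCtrl"
        )
        calls_b = de.call_de(
            de.differential_test(matrix, conditions[0], conditions[2]), policy, sp, "BvsCtrl"
        )
        merged = de.merge_comparisons(calls_a, calls_b)
        out[sp] = pd.concat([calls_a, calls_b, merged], ignore_index=True)
    return out


def de_sets(calls: dict[str, pd.DataFrame]) -> dict[str, dict[str, set[str]]]:
    """comparison -> species -> DE feature ids."""
    out: dict[str, dict[str, set[str]]] = {c: {} for c in COMPARISON_NAMES}
    for sp, df in calls.items():
        for comp in COMPARISON_NAMES:
            sub = df[(df["comparison"] == comp) & (df["direction"] != "not_de")]
            out[comp][sp] = set(sub["feature_id"])
    return out


def stage_coexpress(
    bundle: DatasetBundle, sets: dict, rule: CorrelationRule
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per comparison: lncRNA-mRNA and circRNA-mRNA networks (any sign,
    recorded) and the negative-only miRNA-mRNA network."""
    nets: dict[tuple[str, str], pd.DataFrame] = {}
    for comp in COMPARISON_NAMES:
        samples = comparison_samples(bundle, comp)
        for sponge_sp in ("lncRNA", "circRNA"):
            nets[(comp, f"{sponge_sp}-mRNA")] = coexpression.build_pair_network(
                bundle.expression[sponge_sp], bundle.expression["mRNA"],
                sets[comp][sponge_sp], sets[comp]["mRNA"], rule, samples,
            )
        neg = CorrelationRule(rule.min_abs_r, rule.alpha, "negative")
        nets[(comp, "miRNA-mRNA")] = coexpression.build_pair_network(
            bundle.expression["miRNA"], bundle.expression["mRNA"],
            sets[comp]["miRNA"], sets[comp]["mRNA"], neg, samples,
        )
    return nets


def stage_targets(bundle: DatasetBundle, sets: dict, min_class: str):
    """Seed-site predictions for the union of DE miRNAs against the union
    of DE sponge/mRNA sequences."""
    mirnas = sorted(set().union(*(sets[c]["miRNA"] for c in COMPARISON_NAMES)))
    transcripts: dict[str, str] = {}
    for sp, key in (("lncRNA", "lncRNA"), ("circRNA", "circRNA")):
        wanted = set().union(*(sets[c][sp] for c in COMPARISON_NAMES))
        transcripts.update({t: bundle.sequences[key][t] for t in wanted})
    wanted_mrna = set().union(*(sets[c]["mRNA"] for c in COMPARISON_NAMES))
    transcripts.update({t: bundle.sequences["utr3"][t] for t in wanted_mrna})
    mirna_seqs = {m: bundle.sequences["miRNA"][m] for m in mirnas}
    return targeting.predict_targets(mirna_seqs, transcripts, min_class=min_class)


def stage_cerna(bundle: DatasetBundle, sets: dict, nets: dict, target_map, rule: CorrelationRule):
    """Assemble lncRNA- and circRNA-sponged triplets per comparison."""
    leg_rule = CorrelationRule(rule.min_abs_r, rule.alpha, "negative")
    out: dict[str, list[cerna.CeRNATriplet]] = {}
    for comp in COMPARISON_NAMES:
        samples = comparison_samples(bundle, comp)
        triplets: list[cerna.CeRNATriplet] = []
        for sponge_sp in ("lncRNA", "circRNA"):
            triplets.extend(
                cerna.assemble_triplets(
                    nets[(comp, f"{sponge_sp}-mRNA")],
                    bundle.expression["miRNA"],
                    bundle.expression[sponge_sp],
                    bundle.expression["mRNA"],
                    target_map,
                    mirna_ids=sorted(sets[comp]["miRNA"]),
                    rule=leg_rule,
                    samples=samples,
                )
            )
        out[comp] = sorted(triplets, key=lambda t: (t.sponge_id, t.mirna_id, t.mrna_id))
    return out


def stage_cis(bundle: DatasetBundle, sets: dict, cfg: PipelineConfig) -> pd.DataFrame:
    lnc_union = set().union(*(sets[c]["lncRNA"] for c in COMPARISON_NAMES))
    lncs = [f for f in bundle.features if f.biotype == "lncRNA" and f.id in lnc_union]
    genes = [f for f in bundle.features if f.biotype == "mRNA"]
    return regulation.find_cis_pairs(
        lncs, genes, bundle.expression["lncRNA"], bundle.expression["mRNA"],
        window=cfg.cis_window, min_r=cfg.cis_min_r, holm_alpha=cfg.cis_holm_alpha,
    )


def stage_trans(bundle: DatasetBundle, nets: dict, cfg: PipelineConfig) -> pd.DataFrame:
    edges = pd.concat(
        [nets[(c, "lncRNA-mRNA")] for c in COMPARISON_NAMES], ignore_index=True
    ).drop_duplicates(subset=["node_a", "node_b"])
    return regulation.predict_trans_targets(
        bundle.sequences["lncRNA"], bundle.sequences["utr3"], edges,
        min_len=cfg.trans_min_len, min_identity=cfg.trans_min_identity,
    )


def stage_tf(bundle: DatasetBundle, sets: dict, cfg: PipelineConfig) -> pd.DataFrame:
    lnc_union = set().union(*(sets[c]["lncRNA"] for c in COMPARISON_NAMES))
    lncs = [f for f in bundle.features if f.biotype == "lncRNA" and f.id in lnc_union]
    return regulation.build_tf_network(
        lncs, bundle.pwms, bundle.chromosomes, threshold=cfg.pwm_threshold
    )


def stage_enrich(bundle: DatasetBundle, sets: dict, cfg: PipelineConfig) -> pd.DataFrame:
    frames = []
    for comp in COMPARISON_NAMES:
        res = enrichment.enrich(
            sets[comp]["mRNA"], bundle.gene_sets, min_term_size=cfg.min_term_size
        )
        res.insert(0, "comparison", comp)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _config_key(config: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "simulate": None if config.simulate is None else config.simulate.__dict__,
            "input_dir": str(config.input_dir),
            "thresholds": config.thresholds.__dict__,
            "correlation": config.correlation.__dict__,
            "normalize": config.normalize,
            "min_class": config.min_class,
            "cis": [config.cis_window, config.cis_min_r, config.cis_holm_alpha],
            "trans": [config.trans_min_len, config.trans_min_identity],
            "pwm_threshold": config.pwm_threshold,
            "min_term_size": config.min_term_size,
            "seed": config.seed,
        },
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def _outputs_intact(out: Path, stages: dict) -> bool:
    for entry in stages.values():
        for name, meta in entry.get("outputs", {}).items():
            path = out / name
            if not path.exists() or ("sha256" in meta and _sha256(path) != meta["sha256"]):
                return False
    return True


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Run every stage in dependency order; returns the manifest.

    If a manifest from a previous run with the same configuration exists
    and every recorded output hash still matches, the stages are skipped
    (hash-checked incremental rerun).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    run_key = _config_key(config)
    if manifest_path.exists() and not force:
        previous = json.loads(manifest_path.read_text())
        if previous.get("run_key") == run_key and _outputs_intact(out, previous.get("stages", {})):
            logger.info("inputs unchanged; skipping all stages")
            return previous
    manifest: dict = {"stages": {}, "seed": config.seed, "run_key": run_key}

    def record(stage: str, params: dict, tables: dict[str, pd.DataFrame]) -> None:
        entry = {"params": params, "outputs": {}}
        for name, df in tables.items():
            path = out / name
            _write_tsv(df, path)
            entry["outputs"][name] = {"rows": int(len(df)), "sha256": _sha256(path)}
        manifest["stages"][stage] = entry
        logger.info("stage %s: %s", stage, {k: v["rows"] for k, v in entry["outputs"].items()})

    try:
        # --- simulate / load ------------------------------------------------
        if config.simulate is not None:
            sim = SimulationConfig(**{**config.simulate.__dict__, "seed": config.seed})
            bundle, truth = generate_dataset(sim)
            data_dir = out / "dataset"
            write_dataset(bundle, truth, data_dir)
            manifest["stages"]["simulate"] = {
                "params": {"seed": config.seed},
                "outputs": {
                    f"dataset/{p.name}": {"sha256": _sha256(p)}
                    for p in sorted(data_dir.iterdir())
                },
            }
        else:
            bundle, _ = read_dataset(config.input_dir)

        issues = validate_inputs(bundle)
        if issues:
            raise ValidationError(f"{len(issues)} input issues, first: {issues[:3]}")

        # --- analysis stages ------------------------------------------------
        calls = stage_de(bundle, config.thresholds, config.normalize)
        record(
            "de",
            {"alpha": config.thresholds.alpha, "normalize": config.normalize},
            {"de_calls.tsv": pd.concat(calls.values(), ignore_index=True)},
        )
        # exploratory outputs alongside DE
        pca_res = preprocess.pca(bundle.expression["mRNA"], n_components=2)
        _write_tsv(pca_res.scores.reset_index(names="sample_id"), out / "pca_scores.tsv")
        dendro = preprocess.hierarchical_cluster(bundle.expression["mRNA"], axis="samples")
        (out / "sample_dendrogram.nwk").write_text(dendro.to_newick() + "\n")

        sets = de_sets(calls)
        nets = stage_coexpress(bundle, sets, config.correlation)
        record(
            "coexpress",
            {"min_abs_r": config.correlation.min_abs_r, "alpha": config.correlation.alpha},
            {
                f"edges_{comp}_{kind}.tsv": df
                for (comp, kind), df in sorted(nets.items())
            },
        )

        target_map = stage_targets(bundle, sets, config.min_class)
        record(
            "targets",
            {"min_class": config.min_class},
            {"target_sites.tsv": targeting.sites_to_frame(target_map)},
        )

        triplets = stage_cerna(bundle, sets, nets, target_map, config.correlation)
        record(
            "cerna",
            {"min_abs_r": config.correlation.min_abs_r},
            {
                f"triplets_{comp}.tsv": cerna.triplets_to_frame(tris)
                for comp, tris in triplets.items()
            },
        )

        record("cis", {"window": config.cis_window},
               {"cis_relations.tsv": stage_cis(bundle, sets, config)})
        record("trans",
               {"min_len": config.trans_min_len, "min_identity": config.trans_min_identity},
               {"trans_hits.tsv": stage_trans(bundle, nets, config)})
        record("tf", {"threshold": config.pwm_threshold},
               {"tf_edges.tsv": stage_tf(bundle, sets, config)})
        record("enrich", {"min_term_size": config.min_term_size},
               {"enrichment.tsv": stage_enrich(bundle, sets, config)})
    except ValidationError:
        raise
    except Exception as exc:
        running = [s for s in STAGES if s not in manifest["stages"]]
        stage = running[0] if running else "unknown"
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest["n_stages"] = len(manifest["stages"])
    write_json(manifest, manifest_path)
    return manifest
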