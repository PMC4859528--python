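"""TSV formats, run configuration and end-to-end pipeline orchestration.

Pipeline order mirrors the study design: qPCR miR preprocessing and
differential calling, target vote filtering, microarray preprocessing and
gene-level calling, miR-mRNA regulation calls, optional protein layer with
regulation and mRNA-protein concordance, per-layer pair-ratio index models
with leave-one-out reports, optional stromal partitioning, and clinical
associations of dichotomized miR expression.  Every filter logs its counts
so a run is comparable stage-by-stage with a published analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd
import yaml

from . import integration
from .association import associate, format_p, roc_dichotomize
from .confidence import DEThresholds, call_differential, statements_to_frame
from .containers import CtMatrix, ExpressionMatrix
from .integration import VoteRule, build_regulation_network, network_edge_list
from .pairs import select_pairs
from .prep import (
    ArrayFilterRule,
    DEFAULT_CONTROLS,
    DetectionRule,
    collapse_probe_replicates,
    delta_ct_normalize,
    filter_array_probes,
    filter_detected_mirs,
    quantile_normalize,
)

logger = logging.getLogger("mirindex")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a molecules x samples TSV (first column = molecule id, header
    row = sample ids, numeric body).  Ragged rows, duplicate ids and
    non-numeric cells are rejected with their line number."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    samples = header[1:]
    n_cols = len(header)
    ids, rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != n_cols:
            raise ValueError(
                f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}"
            )
        mol = parts[0]
        if mol in set(ids):
            raise ValueError(f"{path}:{lineno}: duplicate molecule id {mol!r}")
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: non-numeric cell ({e})") from None
        ids.append(mol)
    return pd.DataFrame(rows, index=pd.Index(ids, name=header[0]), columns=samples)


def write_expression_tsv(frame: pd.DataFrame, path) -> None:
    """Write a molecules x samples TSV round-trippable to 12 significant
    digits."""
    frame.to_csv(path, sep="\t", float_format="%.12g")


@dataclass
class StudyBundle:
    """File paths of one study's inputs; protein and stroma are optional."""

    ct_matrix: Optional[Path] = None
    probe_matrix: Optional[Path] = None
    probe_flags: Optional[Path] = None
    probe_to_gene: Optional[Path] = None
    protein_matrix: Optional[Path] = None
    stroma_matrix: Optional[Path] = None
    prediction_map: Optional[Path] = None
    clinical: Optional[Path] = None
    group_column: str = "group"
    control_ids: tuple = DEFAULT_CONTROLS

    @classmethod
    def from_manifest(cls, manifest_path) -> "StudyBundle":
        manifest_path = Path(manifest_path)
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh)
        base = manifest_path.parent
        files = manifest.get("files", {})
        return cls(
            ct_matrix=base / files["ct_matrix"] if "ct_matrix" in files else None,
            probe_matrix=base / files["probe_matrix"] if "probe_matrix" in files else None,
            probe_flags=base / files["probe_flags"] if "probe_flags" in files else None,
            probe_to_gene=base / files["probe_to_gene"] if "probe_to_gene" in files else None,
            protein_matrix=base / files["protein_matrix"] if "protein_matrix" in files else None,
            stroma_matrix=base / files["stroma_matrix"] if "stroma_matrix" in files else None,
            prediction_map=base / files["prediction_map"] if "prediction_map" in files else None,
            clinical=base / files["clinical"] if "clinical" in files else None,
            control_ids=tuple(manifest.get("controls", DEFAULT_CONTROLS)),
        )


@dataclass
class RunConfig:
    """All pipeline constants in one serializable object; the defaults
    encode the study's thresholds (detection limit 38, 60% / 30% filters,
    confidence 0.90 for miRs and 0.80 for genes/proteins, 3-of-7 votes,
    at most 4 index pairs)."""

    detection: DetectionRule = field(default_factory=DetectionRule)
    array_filter: ArrayFilterRule = field(default_factory=ArrayFilterRule)
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    votes: VoteRule = field(default_factory=VoteRule)
    max_pairs: int = 4
    min_sensitivity: float = 0.85
    min_specificity: float = 0.85
    association_test: str = "pearson-chi2"
    seed: int = 0

    def to_yaml(self, path) -> None:
        payload = {
            "detection": vars(self.detection).copy(),
            "array_filter": vars(self.array_filter).copy(),
            "thresholds": vars(self.thresholds).copy(),
            "votes": vars(self.votes).copy(),
            "max_pairs": self.max_pairs,
            "min_sensitivity": self.min_sensitivity,
            "min_specificity": self.min_specificity,
            "association_test": self.association_test,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            detection=DetectionRule(**payload.get("detection", {})),
            array_filter=ArrayFilterRule(**payload.get("array_filter", {})),
            thresholds=DEThresholds(**payload.get("thresholds", {})),
            votes=VoteRule(**payload.get("votes", {})),
            max_pairs=payload.get("max_pairs", 4),
            min_sensitivity=payload.get("min_sensitivity", 0.85),
            min_specificity=payload.get("min_specificity", 0.85),
            association_test=payload.get("association_test", "pearson-chi2"),
            seed=payload.get("seed", 0),
        )


DICHOTOMOUS_CLINICAL = ("tnm", "tumor_size", "grade", "lymph_nodes")


def _index_stage(name, statements, matrix, groups, config, out, log):
    """Fit a per-layer pair-ratio index model and write model + report."""
    try:
        model, report = select_pairs(
            statements, matrix, groups,
            max_pairs=config.max_pairs,
            min_sensitivity=config.min_sensitivity,
            min_specificity=config.min_specificity,
        )
    except ValueError as e:
        log(f"index[{name}]: skipped ({e})")
        return None
    pd.DataFrame(
        [
            {"rank": r + 1, "up_id": p.up_id, "down_id": p.down_id,
             "score": round(p.score, 6), "cutoff": model.cutoff,
             "orientation": model.orientation, "warning": model.warning}
            for r, p in enumerate(model.pairs)
        ]
    ).to_csv(out / f"index_model_{name}.tsv", sep="\t", index=False)
    report.per_sample.rename_axis("sample").to_csv(
        out / f"index_report_{name}.tsv", sep="\t", float_format="%.12g"
    )
    log(
        f"index[{name}]: {len(model.pairs)} pair(s), leave-one-out "
        f"sensitivity={report.sensitivity:.3f} specificity={report.specificity:.3f}"
        f"{' (targets unmet)' if model.warning else ''}"
    )
    return model, report


def run_pipeline(bundle: StudyBundle, config: RunConfig, out_dir) -> Path:
    """Run every applicable stage, writing report TSVs and a counts log.

    Optional layers are skipped with explicit log lines when their inputs
    are missing from the bundle.  Deterministic for fixed inputs/config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    if bundle.clinical is None:
        raise PipelineError("clinical", "bundle has no clinical table")
    clinical = pd.read_csv(bundle.clinical, sep="\t", index_col=0)
    if bundle.group_column not in clinical.columns:
        raise PipelineError(
            "clinical", f"group column {bundle.group_column!r} missing"
        )
    groups = clinical[bundle.group_column]
    log(f"samples: {len(groups)} in groups {dict(groups.value_counts())}")

    mir_statements = None
    mir_expr = None
    if bundle.ct_matrix is not None:
        try:
            ct_frame = read_expression_tsv(bundle.ct_matrix)
            ct = CtMatrix(ct_frame, control_ids=[c for c in bundle.control_ids
                                                 if c in ct_frame.index])
            retained, excluded = filter_detected_mirs(ct, config.detection)
            log(f"qpcr: {len(excluded)} of {len(ct.mir_ids)} miRs excluded by the "
                f"detection rule (> {config.detection.detection_limit} CT in more "
                f"than {config.detection.max_undetected_fraction:.0%} of samples)")
            mir_expr = delta_ct_normalize(retained, config.detection,
                                          groups=groups)
            mir_statements = call_differential(mir_expr, config.thresholds)
            n_de = sum(s.de_flag for s in mir_statements)
            log(f"qpcr: {n_de} miRs differentially expressed at confidence >= "
                f"{config.thresholds.tau_mir}")
            statements_to_frame(mir_statements, groups_pair(groups)).to_csv(
                out / "mir_statements.tsv", sep="\t", index=False
            )
        except (ValueError, KeyError) as e:
            raise PipelineError("qpcr", str(e)) from e
    else:
        log("qpcr: skipped (no CT matrix in bundle)")

    targets = None
    if bundle.prediction_map is not None:
        try:
            pred = pd.read_csv(bundle.prediction_map, sep="\t")
            targets = integration.vote_filter_targets(pred, config.votes)
            n_pairs = sum(len(v) for v in targets.values())
            log(f"targets: {n_pairs} (miR, target) pairs retained with >= "
                f"{config.votes.min_sources} of {config.votes.total_sources} votes")
        except ValueError as e:
            raise PipelineError("target-votes", str(e)) from e
    else:
        log("targets: skipped (no prediction map in bundle)")

    gene_statements = None
    gene_expr = None
    if bundle.probe_matrix is not None and bundle.probe_to_gene is not None:
        try:
            probes = read_expression_tsv(bundle.probe_matrix)
            p2g = pd.read_csv(bundle.probe_to_gene, sep="\t", index_col=0)["gene"]
            if bundle.probe_flags is not None:
                flags = read_expression_tsv(bundle.probe_flags).astype(int)
                kept = filter_array_probes(probes, flags, groups,
                                           config.array_filter)
                log(f"array: {len(probes) - len(kept)} of {len(probes)} probes "
                    f"removed by the {config.array_filter.max_flagged_fraction:.0%} "
                    "per-group flag rule")
            else:
                kept = probes
                log("array: no flags matrix, probe filter skipped")
            genes, dropped = collapse_probe_replicates(kept, p2g)
            log(f"array: {genes.shape[0]} genes after replicate collapsing "
                f"({len(dropped)} genes lost all probes)")
            gene_expr = quantile_normalize(
                ExpressionMatrix(genes, "log2", "array", groups)
            )
            gene_statements = call_differential(gene_expr, config.thresholds)
            n_de = sum(s.de_flag for s in gene_statements)
            log(f"array: {n_de} genes differentially expressed at confidence >= "
                f"{config.thresholds.tau_gene}")
            statements_to_frame(gene_statements, groups_pair(groups)).to_csv(
                out / "gene_statements.tsv", sep="\t", index=False
            )
        except (ValueError, KeyError) as e:
            raise PipelineError("array", str(e)) from e
    else:
        log("array: skipped (no probe matrix / probe map in bundle)")

    if mir_statements and gene_statements and targets:
        calls = integration.call_regulation(mir_statements, gene_statements,
                                            targets, layer="mRNA")
        n_inv = sum(c.relation == integration.INVERSE for c in calls)
        log(f"regulation[mRNA]: {len(calls)} calls, {n_inv} inverse, "
            f"{len(calls) - n_inv} concordant")
        _write_calls(calls, out / "regulation_mrna.tsv")
        graph = build_regulation_network(calls)
        network_edge_list(graph).to_csv(out / "network_edges.tsv", sep="\t",
                                        index=False)
        nx.write_graphml(graph, out / "network.graphml")

    protein_statements = None
    protein_expr = None
    if bundle.protein_matrix is not None:
        try:
            prot = read_expression_tsv(bundle.protein_matrix)
            protein_expr = ExpressionMatrix(prot, "linear", "protein",
                                            groups.reindex(prot.columns))
            protein_statements = call_differential(protein_expr, config.thresholds)
            n_de = sum(s.de_flag for s in protein_statements)
            log(f"protein: {n_de} proteins differentially expressed at confidence "
                f">= {config.thresholds.tau_protein}")
            statements_to_frame(protein_statements, groups_pair(groups)).to_csv(
                out / "protein_statements.tsv", sep="\t", index=False
            )
        except (ValueError, KeyError) as e:
            raise PipelineError("protein", str(e)) from e
    else:
        log("protein: skipped (no protein matrix in bundle)")

    if mir_statements and protein_statements and targets:
        pcalls = integration.call_regulation(mir_statements, protein_statements,
                                             targets, layer="protein")
        n_inv = sum(c.relation == integration.INVERSE for c in pcalls)
        log(f"regulation[protein]: {len(pcalls)} calls, {n_inv} inverse, "
            f"{len(pcalls) - n_inv} concordant")
        _write_calls(pcalls, out / "regulation_protein.tsv")

    if gene_statements and protein_statements:
        gene_by_id = {s.molecule: s for s in gene_statements}
        rows = []
        for ps in protein_statements:
            gs = gene_by_id.get(ps.molecule)
            if gs is None or not ps.de_flag:
                continue
            pd_dir = integration.direction_token(ps)
            gd_dir = integration.direction_token(gs)
            if pd_dir is None or gd_dir is None:
                continue
            pair = integration.assess_concordance(
                ps.molecule, pd_dir, ps.confidence, gd_dir, gs.confidence,
                tau=config.thresholds.tau_gene,
            )
            rows.append(vars(pair))
        pd.DataFrame(rows).to_csv(out / "concordance.tsv", sep="\t", index=False)
        n_hc = sum(r["verdict"] == "concordant-high-confidence" for r in rows)
        log(f"concordance: {len(rows)} molecules on both layers, {n_hc} "
            "concordant at high confidence")

    # per-layer index models
    if mir_statements is not None and mir_expr is not None:
        _index_stage("mir", mir_statements, mir_expr.values, groups, config,
                     out, log)
    if gene_statements is not None and gene_expr is not None:
        _index_stage("gene", gene_statements, gene_expr.values, groups, config,
                     out, log)
    if protein_statements is not None and protein_expr is not None:
        _index_stage("protein", protein_statements, protein_expr.values,
                     groups.reindex(protein_expr.values.columns), config, out, log)

    if bundle.stroma_matrix is not None and gene_statements is not None:
        try:
            stroma = read_expression_tsv(bundle.stroma_matrix)
            stroma_expr = quantile_normalize(
                ExpressionMatrix(stroma, "log2", "stroma-array",
                                 groups.reindex(stroma.columns))
            )
            stroma_statements = call_differential(stroma_expr, config.thresholds)
            stroma_de = {s.molecule for s in stroma_statements if s.de_flag}
            tumor_de = {s.molecule for s in gene_statements if s.de_flag}
            shared, exclusive = integration.partition_stromal_genes(
                stroma_de, tumor_de
            )
            log(f"stroma: {len(stroma_de)} DE stromal genes; {len(shared)} shared "
                f"with whole tumor, {len(exclusive)} stroma-exclusive")
            pd.Series(sorted(shared), name="gene").to_csv(
                out / "stroma_shared.tsv", sep="\t", index=False)
            pd.Series(sorted(exclusive), name="gene").to_csv(
                out / "stroma_exclusive.tsv", sep="\t", index=False)
            _index_stage("stroma", stroma_statements, stroma_expr.values,
                         groups.reindex(stroma_expr.values.columns), config,
                         out, log)
        except (ValueError, KeyError) as e:
            raise PipelineError("stroma", str(e)) from e
    else:
        log("stroma: skipped (no stroma matrix in bundle)")

    # clinical associations of dichotomized miR expression
    if mir_statements is not None and mir_expr is not None:
        assoc_rows = []
        de_mirs = [s.molecule for s in mir_statements if s.de_flag]
        for mir in de_mirs:
            values = mir_expr.values.loc[mir]
            _, status = roc_dichotomize(values, groups.reindex(values.index))
            for var in DICHOTOMOUS_CLINICAL:
                if var not in clinical.columns:
                    continue
                try:
                    table, test, n_dropped = associate(
                        status, clinical[var], method=config.association_test
                    )
                except ValueError as e:
                    log(f"association[{mir} x {var}]: skipped ({e})")
                    continue
                assoc_rows.append(
                    {"mir": mir, "variable": var,
                     "a": table.iloc[0, 0], "b": table.iloc[0, 1],
                     "c": table.iloc[1, 0], "d": table.iloc[1, 1],
                     "n_dropped": n_dropped, "method": test.method,
                     "p": test.p, "p_display": format_p(test.p)}
                )
        pd.DataFrame(assoc_rows).to_csv(out / "associations.tsv", sep="\t",
                                        index=False)
        log(f"associations: {len(assoc_rows)} (miR, variable) tests written")

    (out / "pipeline_log.txt").write_text("\n".join(log_lines) + "\n")
    return out


def groups_pair(groups: pd.Series) -> tuple:
    uniq = list(dict.fromkeys(groups))
    return tuple(uniq[:2]) if len(uniq) >= 2 else (str(uniq[0]), "other")


def _write_calls(calls, path) -> None:
    pd.DataFrame([vars(c) for c in calls]).to_csv(path, sep="\t", index=False)
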