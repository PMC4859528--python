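"""Integration of miR direction statements with target gene/protein layers.

Predicted miR-target pairs are first vote-filtered (retained when supported
by at least ``min_sources`` of the prediction sources).  For every retained
pair whose members are both flagged differentially expressed, a regulation
call is made: *inverse* when the miR and its target moved in opposite
directions between the groups (the canonical repressive mode), *concordant*
when they moved together.  Protein-level calls use the same logic against
the list of regulator miRs per protein: a protein counts as inversely
regulated when ANY of its differential regulators opposes its direction.
mRNA-protein concordance for a molecule requires the same direction on both
layers with both confidences at or above a threshold.

The module also ships three small curated reference tables from a published
ER+ breast tumor study comparing early-onset (YA) with late-onset (MA)
patients: the 24-protein panel with regulator-miR directions, the
eight-molecule protein-vs-mRNA comparison, and per-miR 2x2 clinical
contingency counts.  They power offline worked examples and regression
tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .confidence import DIRECTION_GREATER, DIRECTION_LESS, ConfidenceStatement

UP = "up"
DOWN = "down"
INVERSE = "inverse"
CONCORDANT = "concordant"


def direction_token(statement: ConfidenceStatement) -> Optional[str]:
    """Map a direction statement to "up"/"down" in the first group."""
    if statement.direction == DIRECTION_GREATER:
        return UP
    if statement.direction == DIRECTION_LESS:
        return DOWN
    return None


@dataclass(frozen=True)
class VoteRule:
    """Retain a predicted miR-target pair supported by >= min_sources of
    total_sources prediction databases."""

    min_sources: int = 3
    total_sources: int = 7

    def __post_init__(self) -> None:
        if not (1 <= self.min_sources <= self.total_sources):
            raise ValueError(
                "min_sources must satisfy 1 <= min_sources <= total_sources"
            )


@dataclass
class RegulationCall:
    """A (miR, target) regulation call on one layer."""

    mir: str
    target: str
    layer: str  # "mRNA", "protein" or "stromal-mRNA"
    mir_direction: str
    target_direction: str
    relation: str

    def __post_init__(self) -> None:
        for d in (self.mir_direction, self.target_direction):
            if d not in (UP, DOWN):
                raise ValueError(f"direction must be 'up' or 'down', got {d!r}")
        expected = INVERSE if self.mir_direction != self.target_direction else CONCORDANT
        if self.relation != expected:
            raise ValueError(
                f"relation {self.relation!r} inconsistent with directions "
                f"({self.mir_direction}, {self.target_direction})"
            )


@dataclass
class ConcordancePair:
    """Protein-vs-mRNA direction comparison for one molecule."""

    molecule: str
    protein_direction: str
    protein_confidence: float
    gene_direction: str
    gene_confidence: Optional[float]
    verdict: str  # "concordant-high-confidence" or "not-concordant"
    confidence_missing: bool = False


def vote_filter_targets(
    prediction_map: pd.DataFrame, rule: VoteRule = VoteRule()
) -> dict:
    """Vote-filter a (mir, target, source) record table.

    Returns a dict miR -> set of retained targets (support >= min_sources).
    Duplicate (mir, target, source) triples are rejected.
    """
    if prediction_map.empty:
        raise ValueError("prediction map is empty")
    cols = ["mir", "target", "source"]
    missing = [c for c in cols if c not in prediction_map.columns]
    if missing:
        raise ValueError(f"prediction map lacks columns: {missing}")
    if prediction_map.duplicated(subset=cols).any():
        raise ValueError("duplicate (mir, target, source) records")
    support = prediction_map.groupby(["mir", "target"])["source"].nunique()
    kept = support[support >= rule.min_sources]
    out: dict = {}
    for (mir, target) in kept.index:
        out.setdefault(mir, set()).add(target)
    return out


def call_regulation(
    mir_statements: Sequence[ConfidenceStatement],
    target_statements: Sequence[ConfidenceStatement],
    targets: Mapping[str, set],
    layer: str = "mRNA",
) -> list:
    """Regulation calls for every de-flagged (miR, target) pair in the map.

    Both members must be de-flagged with a determinate direction; pairs with
    an indeterminate member are omitted.
    """
    mir_dir = {}
    for s in mir_statements:
        if s.de_flag:
            d = direction_token(s)
            if d is not None:
                mir_dir[s.molecule] = d
    tgt_dir = {}
    for s in target_statements:
        if s.de_flag:
            d = direction_token(s)
            if d is not None:
                tgt_dir[s.molecule] = d
    calls = []
    for mir, tset in targets.items():
        if mir not in mir_dir:
            continue
        for target in sorted(tset):
            if target not in tgt_dir:
                continue
            md, td = mir_dir[mir], tgt_dir[target]
            relation = INVERSE if md != td else CONCORDANT
            calls.append(RegulationCall(mir, target, layer, md, td, relation))
    return calls


def classify_protein_regulation(
    protein_direction: str, regulator_directions: Sequence[str]
) -> str:
    """Inverse iff ANY regulator miR direction opposes the protein's.

    A protein with mixed-direction regulators therefore counts as inverse;
    only a protein whose differential regulators all move with it is called
    concordant.
    """
    if not regulator_directions:
        raise ValueError("regulator list must be nonempty")
    for d in (protein_direction, *regulator_directions):
        if d not in (UP, DOWN):
            raise ValueError(f"direction must be 'up' or 'down', got {d!r}")
    if any(d != protein_direction for d in regulator_directions):
        return INVERSE
    return CONCORDANT


def assess_concordance(
    molecule: str,
    protein_direction: str,
    protein_confidence: float,
    gene_direction: str,
    gene_confidence: Optional[float],
    tau: float = 0.80,
) -> ConcordancePair:
    """Concordant-high-confidence iff directions agree and both confidences
    reach tau.  A missing gene confidence (e.g. a target quantified only by
    qPCR without a confidence statement) can never reach the threshold and
    is flagged on the result."""
    missing = gene_confidence is None or pd.isna(gene_confidence)
    ok = (
        protein_direction == gene_direction
        and protein_confidence >= tau
        and not missing
        and gene_confidence >= tau
    )
    return ConcordancePair(
        molecule,
        protein_direction,
        protein_confidence,
        gene_direction,
        None if missing else float(gene_confidence),
        "concordant-high-confidence" if ok else "not-concordant",
        confidence_missing=missing,
    )


def partition_stromal_genes(
    stroma_de: Iterable[str], whole_tumor_de: Iterable[str]
) -> tuple[set, set]:
    """Split a stromal DE gene set into (shared with whole tumor, stroma-exclusive)."""
    stroma = set(stroma_de)
    whole = set(whole_tumor_de)
    return stroma & whole, stroma - whole


def build_regulation_network(calls: Sequence[RegulationCall]) -> nx.DiGraph:
    """Deduplicated miR -> target regulation graph.

    Node attribute ``kind`` is "mir" or "target"; edge attributes carry the
    relation and a display color class (inverse -> "red",
    concordant -> "black").
    """
    g = nx.DiGraph()
    for c in calls:
        g.add_node(c.mir, kind="mir")
        g.add_node(c.target, kind="target")
        g.add_edge(c.mir, c.target, relation=c.relation,
                   color="red" if c.relation == INVERSE else "black",
                   layer=c.layer)
    return g


def network_edge_list(g: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {"mir": u, "target": v, "relation": d["relation"], "layer": d.get("layer", "")}
        for u, v, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["mir", "target", "relation", "layer"])


# ---------------------------------------------------------------------------
# packaged reference tables (curated printed results of the ER+ study)
# ---------------------------------------------------------------------------

def _load_table(name: str) -> pd.DataFrame:
    with resources.files("mirindex.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_protein_regulator_table() -> pd.DataFrame:
    """24 differential proteins with direction (in the YA group), confidence
    and the regulator miR tokens ("up:miR-9;down:miR-372")."""
    return _load_table("protein_regulators.tsv")


def load_protein_mrna_table() -> pd.DataFrame:
    """Eight molecules measured on both the protein and mRNA layers."""
    return _load_table("protein_mrna_concordance.tsv")


def load_mir_clinical_counts() -> pd.DataFrame:
    """Per-miR 2x2 contingency counts (under/over expression vs dichotomized
    clinical variables) with the reported p-values as strings."""
    return _load_table("mir_clinical_counts.tsv")


def parse_regulator_tokens(tokens: str) -> list:
    """Parse "up:miR-9;down:miR-372" into [(direction, mir), ...]."""
    out = []
    for tok in str(tokens).split(";"):
        tok = tok.strip()
        if not tok:
            continue
        d, mir = tok.split(":", 1)
        if d not in (UP, DOWN):
            raise ValueError(f"bad regulator direction in token {tok!r}")
        out.append((d, mir))
    return out


def classify_reference_proteins() -> pd.DataFrame:
    """Apply the any-opposing-regulator rule to the packaged protein panel."""
    table = load_protein_regulator_table()
    relations = []
    for _, row in table.iterrows():
        regs = [d for d, _ in parse_regulator_tokens(row["regulators"])]
        relations.append(classify_protein_regulation(row["direction"], regs))
    out = table.copy()
    out["relation"] = relations
    return out


def concordant_reference_molecules(tau: float = 0.80) -> list:
    """Molecules concordant at high confidence in the packaged
    protein-vs-mRNA table."""
    table = load_protein_mrna_table()
    hits = []
    for _, row in table.iterrows():
        pair = assess_concordance(
            row["molecule"],
            row["protein_direction"],
            float(row["protein_confidence"]),
            row["gene_direction"],
            row["gene_confidence"],
            tau=tau,
        )
        if pair.verdict == "concordant-high-confidence":
            hits.append(pair.molecule)
    return hits
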