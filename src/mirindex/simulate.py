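"""Two-group multi-platform synthetic study generator with planted truth.

Emulates the data layout of a two-group (early-onset YA vs late-onset MA)
ER+ tumor study: a qPCR CT matrix with endogenous-control rows and
detection-limit censoring, a probe-level log2 microarray with replicate
probes and low-signal flags, a linear-scale protein panel, a miR-target
prediction map with multi-source votes, and a clinical table.  A planted
subset of molecules carries a group median shift so every downstream stage
has ground truth to recover.

Generator choices (simple location-shift Gaussians, no batch effects or
platform-specific noise structure) are stand-ins for real assay noise and
are documented as such in the package docs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .containers import CtMatrix, ExpressionMatrix
from .prep import DEFAULT_CONTROLS

# base-distribution constants (within-group spread per platform)
CT_MEAN, CT_SD = 28.0, 2.0
CTRL_CT_MEAN, CTRL_CT_SD = 24.0, 0.5
ARRAY_MEAN, ARRAY_SD = 8.0, 1.5
PROBE_REP_SD = 0.3
PROTEIN_LOG_MEAN, PROTEIN_LOG_SD = 4.0, 1.0
UNEXPRESSED_FRACTION = 0.15  # of miRs, drawn from the null pool
DIM_GENE_FRACTION = 0.10  # genes with tripled flag probability


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design
    (25 samples per group, 3 endogenous controls, CT detection limit 38,
    3-of-7 style prediction votes)."""

    n_per_group: tuple = (25, 25)
    n_mirs: int = 100
    n_genes: int = 200
    n_proteins: int = 30
    n_controls: int = 3
    planted_de_fraction: float = 0.08
    shift_sd_units: float = 3.0
    detection_limit: float = 38.0
    censor_prob_null: float = 0.75
    n_probe_reps: int = 2
    flag_prob: float = 0.05
    n_sources: int = 7
    targets_per_mir: int = 4
    clinical_effect: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirs", "n_genes", "n_proteins", "n_controls",
                     "n_probe_reps", "n_sources", "targets_per_mir"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if len(self.n_per_group) != 2 or any(n <= 0 for n in self.n_per_group):
            raise ValueError("n_per_group must be two positive integers")
        for name in ("planted_de_fraction", "censor_prob_null", "flag_prob",
                     "clinical_effect"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.shift_sd_units < 0:
            raise ValueError("shift_sd_units must be nonnegative")
        if self.detection_limit <= 0:
            raise ValueError("detection_limit must be positive")


@dataclass
class PlantedTruth:
    """Ground truth: per-molecule direction and shift, true regulated
    (miR, target) pairs with their relation, and clinical association flags."""

    molecules: pd.DataFrame  # molecule, layer, direction (up/down/null), shift
    pairs: pd.DataFrame  # mir, target, relation, planted (bool)
    clinical_associated: dict  # variable -> bool

    def planted_ids(self, layer: str) -> list:
        m = self.molecules
        sel = (m["layer"] == layer) & (m["direction"] != "null")
        return list(m.loc[sel, "molecule"])


@dataclass
class SyntheticDataset:
    """All generated study components, sample-aligned."""

    ct: CtMatrix
    probe_matrix: pd.DataFrame
    probe_flags: pd.DataFrame
    probe_to_gene: pd.Series
    protein: ExpressionMatrix
    prediction_map: pd.DataFrame  # mir, target, source
    clinical: pd.DataFrame  # indexed by sample; includes "group"
    groups: pd.Series

    def __post_init__(self) -> None:
        samples = list(self.ct.values.columns)
        for other in (self.probe_matrix.columns, self.probe_flags.columns,
                      self.protein.values.columns, self.clinical.index):
            if list(other) != samples:
                raise ValueError("sample identifiers differ across components")


def _plant_directions(ids: list, fraction: float) -> pd.DataFrame:
    """First round(fraction*n) molecules are planted, directions alternating
    up/down starting with up."""
    k = int(round(fraction * len(ids)))
    rows = []
    for pos, m in enumerate(ids):
        if pos < k:
            rows.append((m, "up" if pos % 2 == 0 else "down"))
        else:
            rows.append((m, "null"))
    return pd.DataFrame(rows, columns=["molecule", "direction"])


def _group_shift(direction: str, shift: float, group_idx: int) -> float:
    """Signed mean shift for group 1 (the YA-like group); group 2 unshifted."""
    if group_idx != 0 or direction == "null":
        return 0.0
    return shift if direction == "up" else -shift


def simulate_clinical(
    group_labels: pd.Series, clinical_effect: float, seed=None
) -> pd.DataFrame:
    """Clinical table with dichotomous variables whose category probabilities
    are separated by ``clinical_effect`` between the groups, plus the
    continuous/ordinal fields needed for surrogate subtyping.

    clinical_effect=0 makes the groups exchangeable; clinical_effect=1 makes
    each dichotomous variable separate the groups perfectly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    uniq = list(dict.fromkeys(group_labels))
    if len(uniq) != 2:
        raise ValueError(f"expected two groups, got {uniq}")
    is_first = (pd.Series(group_labels) == uniq[0]).to_numpy()
    n = len(group_labels)
    p = np.where(is_first, 0.5 + clinical_effect / 2, 0.5 - clinical_effect / 2)
    out = pd.DataFrame(index=pd.Series(group_labels).index)
    out["group"] = list(group_labels)
    dichotomous = {
        "tnm": ("III-IV", "I-II"),
        "tumor_size": (">=2cm", "<2cm"),
        "grade": ("3", "1-2"),
        "lymph_nodes": ("positive", "negative"),
    }
    for var, (aggressive, indolent) in dichotomous.items():
        hit = rng.random(n) < p
        out[var] = np.where(hit, aggressive, indolent)
    out["er_percent"] = rng.uniform(10, 100, n).round(1)
    out["pr_percent"] = rng.uniform(0, 100, n).round(1)
    out["ki67_percent"] = rng.uniform(0, 60, n).round(1)
    out["her2_score"] = rng.choice(["0", "1+", "2+", "3+"], size=n,
                                   p=[0.4, 0.25, 0.2, 0.15])
    fish = rng.random(n) < 0.3
    out["fish_positive"] = np.where(out["her2_score"] == "2+", fish, pd.NA)
    return out


def simulate_study(config: SimulationConfig) -> tuple[SyntheticDataset, PlantedTruth]:
    """Generate the full multi-platform bundle plus its planted truth.

    Deterministic for a fixed config (the seed is part of the config).
    CTs above the detection limit are emitted as-is; censoring/filtering is
    a downstream preprocessing concern.
    """
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_per_group
    samples = [f"YA{i+1:02d}" for i in range(n1)] + [f"MA{i+1:02d}" for i in range(n2)]
    groups = pd.Series(["YA"] * n1 + ["MA"] * n2, index=samples, name="group")
    group_idx = np.array([0] * n1 + [1] * n2)

    mir_ids = [f"miR-s{i+1:03d}" for i in range(config.n_mirs)]
    gene_ids = [f"GENE{i+1:03d}" for i in range(config.n_genes)]
    prot_ids = [f"PROT{i+1:02d}" for i in range(config.n_proteins)]

    # a zero shift cannot move any median: nothing is truly planted then
    fraction = config.planted_de_fraction if config.shift_sd_units > 0 else 0.0
    mir_truth = _plant_directions(mir_ids, fraction)
    gene_truth = _plant_directions(gene_ids, fraction)
    prot_truth = _plant_directions(prot_ids, fraction)

    # --- qPCR layer (note: up-regulation lowers CT) -----------------------
    n_samples = n1 + n2
    ct = np.empty((config.n_mirs, n_samples))
    for r, (_, row) in enumerate(mir_truth.iterrows()):
        shift_ct = config.shift_sd_units * CT_SD
        mean = np.array(
            [CT_MEAN - _group_shift(row["direction"], shift_ct, g) for g in group_idx]
        )
        ct[r] = rng.normal(mean, CT_SD)
    # a trailing subset of null miRs is essentially unexpressed: each sample
    # exceeds the detection limit with probability censor_prob_null
    null_positions = [i for i, d in enumerate(mir_truth["direction"]) if d == "null"]
    n_unexpressed = min(
        int(round(UNEXPRESSED_FRACTION * config.n_mirs)), len(null_positions)
    )
    unexpressed = null_positions[len(null_positions) - n_unexpressed:] \
        if n_unexpressed else []
    for r in unexpressed:
        censored = rng.random(n_samples) < config.censor_prob_null
        high = rng.uniform(config.detection_limit + 0.5,
                           config.detection_limit + 4.0, n_samples)
        near = rng.normal(config.detection_limit - 2.0, 1.0, n_samples)
        ct[r] = np.where(censored, high, np.clip(near, 1.0, None))
    ct = np.clip(ct, 1.0, None)
    control_ids = [DEFAULT_CONTROLS[i] if i < len(DEFAULT_CONTROLS) else f"CTRL{i+1}"
                   for i in range(config.n_controls)]
    ctrl = rng.normal(CTRL_CT_MEAN, CTRL_CT_SD, (config.n_controls, n_samples))
    ct_frame = pd.DataFrame(
        np.vstack([ct, ctrl]), index=mir_ids + control_ids, columns=samples
    )
    ct_matrix = CtMatrix(ct_frame, control_ids=control_ids)

    # --- microarray layer -------------------------------------------------
    shift_arr = config.shift_sd_units * ARRAY_SD
    gene_level = np.empty((config.n_genes, n_samples))
    for r, (_, row) in enumerate(gene_truth.iterrows()):
        mean = np.array(
            [ARRAY_MEAN + _group_shift(row["direction"], shift_arr, g)
             for g in group_idx]
        )
        gene_level[r] = rng.normal(mean, ARRAY_SD)
    probe_rows, probe_ids, probe_gene = [], [], []
    for r, g in enumerate(gene_ids):
        for rep in range(config.n_probe_reps):
            probe_rows.append(gene_level[r] + rng.normal(0, PROBE_REP_SD, n_samples))
            probe_ids.append(f"{g}_p{rep+1}")
            probe_gene.append(g)
    probe_matrix = pd.DataFrame(np.array(probe_rows), index=probe_ids, columns=samples)
    probe_to_gene = pd.Series(probe_gene, index=probe_ids, name="gene")
    gene_dir_lookup = dict(zip(gene_truth["molecule"], gene_truth["direction"]))
    n_dim = int(round(DIM_GENE_FRACTION * config.n_genes))
    dim_genes = set(g for g in gene_ids[config.n_genes - n_dim:]
                    if gene_dir_lookup[g] == "null")
    flag_p = np.array(
        [min(1.0, 3 * config.flag_prob) if g in dim_genes else config.flag_prob
         for g in probe_gene]
    )
    probe_flags = pd.DataFrame(
        (rng.random((len(probe_ids), n_samples)) < flag_p[:, None]).astype(int),
        index=probe_ids, columns=samples,
    )

    # --- protein layer (log-normal, reported on the linear scale) ---------
    shift_prot = config.shift_sd_units * PROTEIN_LOG_SD
    prot_log = np.empty((config.n_proteins, n_samples))
    for r, (_, row) in enumerate(prot_truth.iterrows()):
        mean = np.array(
            [PROTEIN_LOG_MEAN + _group_shift(row["direction"], shift_prot, g)
             for g in group_idx]
        )
        prot_log[r] = rng.normal(mean, PROTEIN_LOG_SD)
    protein = ExpressionMatrix(
        pd.DataFrame(np.power(2.0, prot_log), index=prot_ids, columns=samples),
        scale="linear", platform="protein", groups=groups,
    )

    # --- prediction map with multi-source votes ---------------------------
    planted_mirs = list(mir_truth.loc[mir_truth["direction"] != "null", "molecule"])
    planted_genes = list(gene_truth.loc[gene_truth["direction"] != "null", "molecule"])
    null_genes = list(gene_truth.loc[gene_truth["direction"] == "null", "molecule"])
    mir_dir = dict(zip(mir_truth["molecule"], mir_truth["direction"]))
    gene_dir = dict(zip(gene_truth["molecule"], gene_truth["direction"]))
    records, pair_rows = [], []
    decoy_cursor = 0
    for mi, mir in enumerate(planted_mirs):
        # planted regulated pairs: >= 3 supporting sources by construction
        for t in range(min(config.targets_per_mir, len(planted_genes))):
            gene = planted_genes[(mi * config.targets_per_mir + t) % len(planted_genes)]
            n_support = int(rng.integers(3, config.n_sources + 1))
            sources = rng.choice(config.n_sources, size=n_support, replace=False)
            for s in sorted(sources):
                records.append((mir, gene, f"src{s+1}"))
            relation = ("inverse" if mir_dir[mir] != gene_dir[gene] else "concordant")
            pair_rows.append((mir, gene, relation, True))
        # decoy pairs: 0-2 supporting sources
        for _ in range(config.targets_per_mir):
            gene = null_genes[decoy_cursor % len(null_genes)]
            decoy_cursor += 1
            n_support = int(rng.integers(0, 3))
            sources = rng.choice(config.n_sources, size=n_support, replace=False)
            for s in sorted(sources):
                records.append((mir, gene, f"src{s+1}"))
            pair_rows.append((mir, gene, "none", False))
    prediction_map = pd.DataFrame(records, columns=["mir", "target", "source"])
    pairs = pd.DataFrame(pair_rows, columns=["mir", "target", "relation", "planted"])
    pairs = pairs.drop_duplicates(subset=["mir", "target"])

    # --- clinical ---------------------------------------------------------
    clinical = simulate_clinical(groups, config.clinical_effect, rng)

    molecules = pd.concat(
        [
            mir_truth.assign(layer="mir"),
            gene_truth.assign(layer="gene"),
            prot_truth.assign(layer="protein"),
        ],
        ignore_index=True,
    )
    shift_of = {"mir": config.shift_sd_units * CT_SD,
                "gene": shift_arr, "protein": shift_prot}
    molecules["shift"] = [
        0.0 if d == "null" else shift_of[layer]
        for d, layer in zip(molecules["direction"], molecules["layer"])
    ]
    truth = PlantedTruth(
        molecules=molecules,
        pairs=pairs,
        clinical_associated={
            v: config.clinical_effect > 0
            for v in ("tnm", "tumor_size", "grade", "lymph_nodes")
        },
    )
    dataset = SyntheticDataset(
        ct=ct_matrix,
        probe_matrix=probe_matrix,
        probe_flags=probe_flags,
        probe_to_gene=probe_to_gene,
        protein=protein,
        prediction_map=prediction_map,
        clinical=clinical,
        groups=groups,
    )
    return dataset, truth


def write_bundle(
    dataset: SyntheticDataset, truth: PlantedTruth, out_dir, seed: Optional[int] = None
) -> Path:
    """Write the bundle as TSV files plus a YAML manifest; returns the
    manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ct_matrix": "ct_matrix.tsv",
        "probe_matrix": "probe_matrix.tsv",
        "probe_flags": "probe_flags.tsv",
        "probe_to_gene": "probe_to_gene.tsv",
        "protein_matrix": "protein_matrix.tsv",
        "prediction_map": "prediction_map.tsv",
        "clinical": "clinical.tsv",
        "truth_molecules": "truth_molecules.tsv",
        "truth_pairs": "truth_pairs.tsv",
    }
    dataset.ct.values.to_csv(out / paths["ct_matrix"], sep="\t")
    dataset.probe_matrix.to_csv(out / paths["probe_matrix"], sep="\t")
    dataset.probe_flags.to_csv(out / paths["probe_flags"], sep="\t")
    dataset.probe_to_gene.rename_axis("probe").to_csv(
        out / paths["probe_to_gene"], sep="\t"
    )
    dataset.protein.values.to_csv(out / paths["protein_matrix"], sep="\t")
    dataset.prediction_map.to_csv(out / paths["prediction_map"], sep="\t", index=False)
    dataset.clinical.rename_axis("sample").to_csv(out / paths["clinical"], sep="\t")
    truth.molecules.to_csv(out / paths["truth_molecules"], sep="\t", index=False)
    truth.pairs.to_csv(out / paths["truth_pairs"], sep="\t", index=False)
    manifest = {
        "seed": seed,
        "controls": list(dataset.ct.control_ids),
        "files": paths,
    }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path
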