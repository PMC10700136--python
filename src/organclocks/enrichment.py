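"""Organ-enriched protein calling and protein-set construction.

Maps plasma proteins to organs of origin using bulk tissue RNA expression.
A gene is called *organ enriched* when its expression in one organ is at
least ``fold_threshold`` (default 4) times higher than in any other organ,
the Human-Protein-Atlas-style rule. Organ-level expression is the maximum
over the organ's subtissues (e.g. all brain regions), and a synthetic
"immune" organ is defined as blood + spleen. The enriched calls, combined
with the proteomics panel after QC, yield mutually exclusive organ protein
sets plus an "organismal" set (QC-passing probes enriched in no organ) and
a "conventional" set (all QC-passing probes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Organs used for clock training by default.
DEFAULT_ORGANS: tuple[str, ...] = (
    "adipose", "artery", "brain", "heart", "immune", "intestine",
    "kidney", "liver", "lung", "muscle", "pancreas",
)

#: Approximate tissue->organ grouping for a GTEx-style tissue vocabulary.
#: The immune organ is defined as blood + spleen; brain collects the
#: individual brain regions. This grouping is an approximation for any
#: particular upstream tissue naming and is fully overridable.
DEFAULT_ORGAN_MAP: dict[str, tuple[str, ...]] = {
    "adipose": ("adipose_subcutaneous", "adipose_visceral"),
    "artery": ("artery_aorta", "artery_coronary", "artery_tibial"),
    "brain": (
        "brain_cortex", "brain_cerebellum", "brain_hippocampus",
        "brain_hypothalamus", "brain_amygdala", "brain_substantia_nigra",
    ),
    "heart": ("heart_atrial_appendage", "heart_left_ventricle"),
    "immune": ("blood", "spleen"),
    "intestine": ("colon_sigmoid", "colon_transverse", "small_intestine"),
    "kidney": ("kidney_cortex", "kidney_medulla"),
    "liver": ("liver",),
    "lung": ("lung",),
    "muscle": ("muscle_skeletal",),
    "pancreas": ("pancreas",),
}


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression with a sample->tissue assignment.

    ``values`` is a genes x samples DataFrame of nonnegative reals (raw
    counts or normalized expression); every column must map to exactly one
    tissue label in ``sample_to_tissue``.
    """

    values: pd.DataFrame
    sample_to_tissue: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        missing = [s for s in self.values.columns if s not in self.sample_to_tissue]
        if missing:
            raise ValueError(f"samples without a tissue assignment: {missing[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def tissues(self) -> set[str]:
        return {self.sample_to_tissue[s] for s in self.values.columns}


def check_organ_map(organ_map: dict[str, tuple[str, ...]]) -> None:
    """Validate disjointness and non-emptiness of an organ->tissues map."""
    seen: dict[str, str] = {}
    for organ, tissues in organ_map.items():
        if len(tissues) == 0:
            raise ValueError(f"organ {organ!r} has no tissues")
        for t in tissues:
            if t in seen:
                raise ValueError(
                    f"tissue {t!r} assigned to both {seen[t]!r} and {organ!r}"
                )
            seen[t] = organ


def normalize_expression(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios (DESeq2-style) size-factor normalization.

    The per-sample size factor is the median, over genes whose geometric
    mean across samples is nonzero, of count / geometric mean; returned
    values are counts divided by the sample's size factor.
    """
    counts = raw.values.to_numpy(dtype=float)
    n_samples = counts.shape[1]
    if n_samples == 1:
        logger.warning("single-sample matrix: size factor fixed at 1, returned unchanged")
        return ExpressionMatrix(raw.values.copy(), dict(raw.sample_to_tissue))
    # reference set: genes with strictly positive counts in every sample
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "every gene has a zero count in some sample: no reference genes "
            "with nonzero geometric mean for median-of-ratios normalization"
        )
    log_counts = np.log(counts[positive])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    size_factors = np.exp(np.median(log_counts - log_geomean, axis=0))
    normalized = raw.values / size_factors
    return ExpressionMatrix(normalized, dict(raw.sample_to_tissue))


def collapse_to_organs(
    expr: ExpressionMatrix,
    organ_map: dict[str, tuple[str, ...]] | None = None,
    tissue_summary: str = "median",
) -> pd.DataFrame:
    """Summarize samples per tissue then take the per-organ maximum.

    Returns a genes x organs DataFrame. Each tissue's samples are reduced
    with ``tissue_summary`` ("median" or "mean"); the organ value is the
    maximum over its subtissues (so e.g. brain = max over brain regions and
    immune = max(blood, spleen)).
    """
    organ_map = DEFAULT_ORGAN_MAP if organ_map is None else organ_map
    check_organ_map(organ_map)
    if tissue_summary not in ("median", "mean"):
        raise ValueError(f"unknown tissue_summary {tissue_summary!r}")
    by_tissue: dict[str, list[str]] = {}
    for sample, tissue in expr.sample_to_tissue.items():
        if sample in expr.values.columns:
            by_tissue.setdefault(tissue, []).append(sample)
    wanted = {t for tissues in organ_map.values() for t in tissues}
    missing = sorted(wanted - set(by_tissue))
    if missing:
        raise ValueError(f"tissues referenced by the organ map but absent: {missing}")

    tissue_values = {}
    for tissue, samples in by_tissue.items():
        if tissue not in wanted:
            continue
        sub = expr.values[samples]
        tissue_values[tissue] = sub.median(axis=1) if tissue_summary == "median" else sub.mean(axis=1)

    organ_cols = {}
    for organ, tissues in organ_map.items():
        organ_cols[organ] = pd.concat([tissue_values[t] for t in tissues], axis=1).max(axis=1)
    return pd.DataFrame(organ_cols, index=expr.values.index)


def call_enriched_genes(
    organ_expr: pd.DataFrame,
    fold_threshold: float = 4.0,
    min_expression: float = 1.0,
) -> pd.DataFrame:
    """Apply the fold-change enrichment rule to a genes x organs matrix.

    A gene is enriched in organ *o* iff *o* holds the unique maximum, the
    maximum is at least ``min_expression``, and it is at least
    ``fold_threshold`` times the second-highest organ value ("at least"
    makes the threshold itself inclusive). A zero second-highest value
    above the floor yields an infinite fold change. An exact tie for the
    maximum means no single dominating organ, hence no call.

    Returns a DataFrame indexed by gene with columns ``enriched_organ``
    (object, None when not enriched), ``fold_change``, ``top_value`` and
    ``second_value``.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if min_expression < 0:
        raise ValueError("min_expression must be nonnegative")
    if organ_expr.shape[1] < 2:
        raise ValueError("need at least 2 organs to call enrichment")

    vals = organ_expr.to_numpy(dtype=float)
    order = np.argsort(vals, axis=1)
    top_idx = order[:, -1]
    rows = np.arange(vals.shape[0])
    top = vals[rows, top_idx]
    second = vals[rows, order[:, -2]]

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(second > 0, top / np.where(second > 0, second, 1.0), np.inf)
    fold = np.where((second == 0) & (top == 0), np.nan, fold)

    tie = top == second  # tie for the maximum: no dominating organ
    enriched = (~tie) & (top >= min_expression) & (fold >= fold_threshold)

    organs = organ_expr.columns.to_numpy()
    out = pd.DataFrame(
        {
            "enriched_organ": np.where(enriched, organs[top_idx], None),
            "fold_change": fold,
            "top_value": top,
            "second_value": second,
        },
        index=organ_expr.index,
    )
    return out


def qc_filter_panel(
    panel: pd.DataFrame,
    max_cv: float = 0.15,
    min_cross_version_r: float = 0.5,
) -> pd.DataFrame:
    """Flag probes passing replicate-CV and cross-assay-version QC.

    ``qc_pass`` requires cv <= max_cv AND cross_version_r >=
    min_cross_version_r. Probes missing a QC column pass that check with a
    logged warning. The default thresholds are repository defaults, not
    values taken from any particular assay release.
    """
    if panel["probe_id"].duplicated().any():
        raise ValueError("duplicate probe ids in panel")
    out = panel.copy()
    passing = np.ones(len(out), dtype=bool)
    for col, ok in (
        ("cv", lambda s: s <= max_cv),
        ("cross_version_r", lambda s: s >= min_cross_version_r),
    ):
        if col in out.columns:
            s = out[col]
            missing = s.isna()
            if missing.any():
                logger.warning("%d probes missing %s: passing that check", missing.sum(), col)
            passing &= ok(s.astype(float)).fillna(True).to_numpy()
        else:
            logger.warning("panel has no %r column: all probes pass that check", col)
    out["qc_pass"] = passing
    return out


@dataclass
class ProteinSetCatalog:
    """Mutually exclusive organ probe sets plus organismal/conventional sets."""

    organ_sets: dict[str, frozenset[str]]
    organismal_set: frozenset[str]
    conventional_set: frozenset[str]
    fold_threshold: float = 4.0

    def __post_init__(self) -> None:
        organs = list(self.organ_sets)
        for i, a in enumerate(organs):
            for b in organs[i + 1:]:
                if self.organ_sets[a] & self.organ_sets[b]:
                    raise ValueError(f"organ sets {a!r} and {b!r} overlap")
            if self.organ_sets[a] & self.organismal_set:
                raise ValueError(f"organ set {a!r} overlaps the organismal set")
        union = frozenset().union(*self.organ_sets.values()) if self.organ_sets else frozenset()
        if (union | self.organismal_set) - self.conventional_set:
            raise ValueError("organ/organismal probes outside the conventional set")

    def model_names(self) -> list[str]:
        return list(self.organ_sets) + ["organismal", "conventional"]

    def probes_for(self, model_name: str) -> frozenset[str]:
        if model_name == "organismal":
            return self.organismal_set
        if model_name == "conventional":
            return self.conventional_set
        return self.organ_sets[model_name]

    def to_dict(self) -> dict:
        return {
            "schema": "organclocks.catalog/1",
            "fold_threshold": self.fold_threshold,
            "organ_sets": {k: sorted(v) for k, v in self.organ_sets.items()},
            "organismal_set": sorted(self.organismal_set),
            "conventional_set": sorted(self.conventional_set),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProteinSetCatalog":
        return cls(
            organ_sets={k: frozenset(v) for k, v in d["organ_sets"].items()},
            organismal_set=frozenset(d["organismal_set"]),
            conventional_set=frozenset(d["conventional_set"]),
            fold_threshold=float(d.get("fold_threshold", 4.0)),
        )


def build_protein_sets(
    enrichment: pd.DataFrame,
    panel: pd.DataFrame,
    organs_in_scope: tuple[str, ...] = DEFAULT_ORGANS,
    fold_threshold: float = 4.0,
) -> ProteinSetCatalog:
    """Combine enrichment calls with the QC-passing panel into a catalog.

    The organismal set contains QC-passing probes whose gene is enriched in
    *no* organ at all (in-scope or not): a gene enriched in an out-of-scope
    organ is organ-specific, hence excluded from the organ-nonspecific set.
    """
    qc = panel[panel["qc_pass"]] if "qc_pass" in panel.columns else panel
    gene_to_organ = enrichment["enriched_organ"]

    organ_sets: dict[str, set[str]] = {o: set() for o in organs_in_scope}
    organismal: set[str] = set()
    conventional: set[str] = set()
    for probe, gene in zip(qc["probe_id"], qc["gene_symbol"]):
        conventional.add(probe)
        organ = gene_to_organ.get(gene) if gene in gene_to_organ.index else None
        if organ is None:
            organismal.add(probe)
        elif organ in organ_sets:
            organ_sets[organ].add(probe)
        # enriched in an out-of-scope organ: neither an organ set nor organismal

    for organ, probes in organ_sets.items():
        if not probes:
            logger.warning("organ %r has an empty protein set", organ)
    return ProteinSetCatalog(
        organ_sets={o: frozenset(s) for o, s in organ_sets.items()},
        organismal_set=frozenset(organismal),
        conventional_set=frozenset(conventional),
        fold_threshold=fold_threshold,
    )
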