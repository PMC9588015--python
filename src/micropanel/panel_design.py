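"""Tumor-informed micro-panel design.

Given a patient's somatic variant table (tumor/normal exome calls), this
module applies the standard post-calling filters, selects the 1-6 variants
that form the patient's personalized ctDNA micro-panel, lays the resulting
amplicons out into primer pools, and flags germline BRCA1/BRCA2 status from
a supplied pathogenicity classification table.

The selection heuristic is tumor-informed: every non-silent TP53 variant is
included (TP53 is mutated in the large majority of triple-negative breast
tumors), supplemented by the remaining variants with the highest tissue
variant allele fraction, up to the panel size cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

#: Consequence classes accepted on input variants.
CONSEQUENCE_CLASSES = frozenset(
    {
        "silent",
        "missense",
        "nonsense",
        "frameshift",
        "splice",
        "inframe_indel",
        "other_nonsilent",
    }
)

#: Half-width of the amplicon interval placed around each selected locus (bp).
AMPLICON_FLANK = 75


class PanelDesignError(ValueError):
    """Raised when a panel cannot be designed for a patient."""


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic variant from a tumor/normal comparison.

    Coordinates are 1-based (``pos``); ``tissue_vaf`` is the allele fraction
    observed in the tumor biopsy.  The remaining covariates
    (``population_af``, ``mq0_fraction``, ``depth``, ``known_variant``,
    ``confidence``) drive the post-calling filters.
    """

    patient_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene_symbol: str
    consequence_class: str
    tissue_vaf: float
    depth: int = 0
    population_af: float = 0.0
    mq0_fraction: float = 0.0
    known_variant: bool = False
    confidence: str = "high"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (got {self.pos})")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        for name in ("tissue_vaf", "population_af", "mq0_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {v})")
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValueError(
                f"unknown consequence_class {self.consequence_class!r}"
            )

    @property
    def is_nonsilent_tp53(self) -> bool:
        return self.gene_symbol == "TP53" and self.consequence_class != "silent"

    @property
    def locus(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the post-calling somatic variant filters.

    The filters remove previously known variants, variants with high
    population allele frequency, variants supported by a high fraction of
    zero-mapping-quality reads, low-depth variants, and low-confidence
    variants.  Numeric defaults are conventional somatic-filtering choices
    and are fully configurable.
    """

    max_population_af: float = 0.001
    max_mq0_fraction: float = 0.10
    min_depth: int = 20
    exclude_known: bool = True
    exclude_low_confidence: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_population_af <= 1.0:
            raise ValueError("max_population_af must be in [0, 1]")
        if not 0.0 <= self.max_mq0_fraction <= 1.0:
            raise ValueError("max_mq0_fraction must be in [0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass(frozen=True)
class PanelConfig:
    """Micro-panel sizing rules.

    ``target_size`` is the nominal panel size (all non-silent TP53 variants
    plus up to ``n_extra_top_vaf`` highest-VAF others); ``max_size`` caps the
    panel at six amplicons; ``max_primer_pairs_per_pool`` caps primer pool
    occupancy.
    """

    target_size: int = 4
    max_size: int = 6
    min_size: int = 1
    n_extra_top_vaf: int = 3
    max_primer_pairs_per_pool: int = 100

    def __post_init__(self) -> None:
        if not self.min_size <= self.target_size <= self.max_size <= 6:
            raise ValueError(
                "require min_size <= target_size <= max_size <= 6"
            )
        if self.max_primer_pairs_per_pool < 1:
            raise ValueError("max_primer_pairs_per_pool must be >= 1")


@dataclass(frozen=True)
class PanelTarget:
    """One selected variant with its amplicon placement.

    ``amplicon_start``/``amplicon_end`` are 0-based half-open genomic
    coordinates; the variant locus lies strictly inside.
    """

    variant: SomaticVariant
    amplicon_start: int
    amplicon_end: int
    primer_pair_id: str

    @property
    def amplicon_id(self) -> str:
        v = self.variant
        return f"{v.patient_id}:{v.chrom}:{v.pos}:{v.ref_allele}>{v.alt_allele}"

    @property
    def locus_offset(self) -> int:
        """0-based offset of the variant position within the amplicon."""
        return (self.variant.pos - 1) - self.amplicon_start


@dataclass
class PanelDesign:
    """A patient's micro-panel: 1-6 targets plus a pool assignment."""

    patient_id: str
    targets: list[PanelTarget]
    pool_id: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.targets) <= 6:
            raise ValueError("panel must hold 1-6 targets")
        for t in self.targets:
            if not t.amplicon_start <= (t.variant.pos - 1) < t.amplicon_end:
                raise ValueError("variant locus outside its amplicon")

    @property
    def size(self) -> int:
        return len(self.targets)


def filter_variants(
    variants: list[SomaticVariant], cfg: FilterConfig | None = None
) -> list[SomaticVariant]:
    """Apply the post-calling somatic filters, preserving input order.

    A variant passes when it is not previously known (if ``exclude_known``),
    its population allele frequency, zero-mapping-quality read fraction and
    depth meet the thresholds, and it is not low confidence (if
    ``exclude_low_confidence``).
    """
    cfg = cfg or FilterConfig()
    kept: list[SomaticVariant] = []
    for v in variants:
        if cfg.exclude_known and v.known_variant:
            continue
        if v.population_af > cfg.max_population_af:
            continue
        if v.mq0_fraction > cfg.max_mq0_fraction:
            continue
        if v.depth < cfg.min_depth:
            continue
        if cfg.exclude_low_confidence and v.confidence == "low":
            continue
        kept.append(v)
    return kept


def _vaf_rank_key(v: SomaticVariant) -> tuple:
    # Descending VAF, ties broken by higher depth then ascending (chrom, pos):
    # makes selection a deterministic, order-independent function of the table.
    return (-v.tissue_vaf, -v.depth, v.chrom, v.pos)


def select_panel(
    variants: list[SomaticVariant], cfg: PanelConfig | None = None
) -> PanelDesign:
    """Select a patient's micro-panel from filtered variants.

    All non-silent TP53 variants are taken first; remaining slots up to
    ``target_size`` are filled by the other variants in descending tissue
    VAF.  The panel never exceeds ``max_size``; if non-silent TP53 variants
    alone exceed it, the highest-VAF six are kept.
    """
    cfg = cfg or PanelConfig()
    if not variants:
        raise PanelDesignError("no variants available for panel design")
    patient_ids = {v.patient_id for v in variants}
    if len(patient_ids) != 1:
        raise PanelDesignError(
            f"panel selection expects one patient, got {sorted(patient_ids)}"
        )
    patient_id = patient_ids.pop()

    tp53 = sorted((v for v in variants if v.is_nonsilent_tp53), key=_vaf_rank_key)
    others = sorted(
        (v for v in variants if not v.is_nonsilent_tp53), key=_vaf_rank_key
    )

    selected = tp53[: cfg.max_size]
    if len(tp53) > cfg.max_size:
        logger.warning(
            "patient %s: %d non-silent TP53 variants exceed max panel size %d; "
            "keeping the top-VAF %d",
            patient_id, len(tp53), cfg.max_size, cfg.max_size,
        )
    n_wanted = max(cfg.target_size, len(selected))
    n_wanted = min(n_wanted, cfg.max_size)
    n_extra = min(n_wanted - len(selected), cfg.n_extra_top_vaf, len(others))
    selected = selected + others[:max(n_extra, 0)]

    targets = []
    for v in selected:
        pos0 = v.pos - 1
        start = max(0, pos0 - AMPLICON_FLANK)
        end = pos0 + AMPLICON_FLANK
        targets.append(
            PanelTarget(
                variant=v,
                amplicon_start=start,
                amplicon_end=end,
                primer_pair_id=f"{patient_id}:{v.chrom}:{v.pos}",
            )
        )
    return PanelDesign(patient_id=patient_id, targets=targets)


def build_pools(
    panels: list[PanelDesign], cfg: PanelConfig | None = None
) -> dict[int, list[str]]:
    """Assign panels to primer pools by greedy first-fit.

    All of a patient's primer pairs stay in a single pool; no pool exceeds
    ``max_primer_pairs_per_pool`` pairs.  Returns ``{pool_id: [patient_id,
    ...]}`` and sets ``pool_id`` on each panel in place.
    """
    cfg = cfg or PanelConfig()
    cap = cfg.max_primer_pairs_per_pool
    pools: dict[int, list[str]] = {}
    loads: dict[int, int] = {}
    for panel in panels:
        if panel.size > cap:
            raise PanelDesignError(
                f"panel for {panel.patient_id} ({panel.size} pairs) exceeds "
                f"pool capacity {cap}"
            )
        placed = False
        for pid in sorted(loads):
            if loads[pid] + panel.size <= cap:
                pools[pid].append(panel.patient_id)
                loads[pid] += panel.size
                panel.pool_id = pid
                placed = True
                break
        if not placed:
            pid = len(pools) + 1
            pools[pid] = [panel.patient_id]
            loads[pid] = panel.size
            panel.pool_id = pid
    return pools


PATHOGENIC_CLASSES = {"Pathogenic", "Likely pathogenic"}
BENIGN_CLASSES = {"Benign", "Likely benign"}


def flag_brca_germline(
    germline_variants: list[SomaticVariant],
    classification_table: dict[tuple[str, int, str, str], str | list[str]],
) -> str:
    """Flag germline BRCA1/BRCA2 carrier status for one patient.

    ``classification_table`` maps (chrom, pos, ref, alt) to a pathogenicity
    class (or a list of classes when sources disagree).  Status is positive
    when at least one BRCA1/BRCA2 variant is classified Pathogenic or Likely
    pathogenic; a variant carrying both pathogenic and benign classifications
    yields ``indeterminate``.
    """
    status = "negative"
    indeterminate = False
    for v in germline_variants:
        if v.gene_symbol not in ("BRCA1", "BRCA2"):
            continue
        classes = classification_table.get(v.locus)
        if classes is None:
            continue
        if isinstance(classes, str):
            classes = [classes]
        has_path = any(c in PATHOGENIC_CLASSES for c in classes)
        has_benign = any(c in BENIGN_CLASSES for c in classes)
        if has_path and has_benign:
            indeterminate = True
        elif has_path:
            return f"positive_{v.gene_symbol}"
    return "indeterminate" if indeterminate else status
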