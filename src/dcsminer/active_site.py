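"""Active-site residue mapping and rule-based product prediction.

The Class II active site of ent-CPP synthases carries a histidine–asparagine
dyad (inside LHS and PNV motif contexts, in the γ-domain) that coordinates
the water acting as catalytic base; the Class I (kaurene synthase) active
site carries a plant-type key isoleucine inside a PIx context, with the
bacterial-type key position four residues (one helical turn) upstream.
Sites are transferred from an annotated reference to a query by global
pairwise alignment, and product outcomes of wild type and anchored mutants
are predicted from a fixed rule table of observed outcomes for the
CPS–KS lineage.  The table is an annotation lookup, not a mechanistic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping

from .align_phylo import Alignment, pairwise_align
from .motif_engine import (BUILTIN_MOTIFS, ClassIStatus, ClassIIStatus,
                           MotifStatus)
from .seqio import ProteinRecord, read_fasta, read_tsv


@dataclass(frozen=True)
class SiteAnnotation:
    name: str
    position: int           # 1-based on the reference
    residue: str
    context_motif: str | None   # motif whose match must cover the site
    context_offset: int      # 1-based offset of the site within that motif


@dataclass(frozen=True)
class ActiveSiteProfile:
    """Mapped active-site positions on a query (None when unalignable)."""

    dyad_his: int | None
    dyad_asn: int | None
    plant_type_ile: int | None
    bacterial_type_position: int | None
    residue_states: Mapping[str, str]
    context_mismatch: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.plant_type_ile is not None
                and self.bacterial_type_position is not None
                and self.bacterial_type_position != self.plant_type_ile - 4):
            raise ValueError("bacterial-type position must be plant-type Ile - 4")


def load_reference_fixture() -> tuple[ProteinRecord, list[SiteAnnotation]]:
    """Load the packaged synthetic annotated CPS–KS reference fixture
    (FASTA plus sidecar site TSV)."""
    data = resources.files("dcsminer") / "data"
    with resources.as_file(data / "synthetic_csedcs_like.fasta") as path:
        record = read_fasta(path)[0]
    with resources.as_file(data / "synthetic_csedcs_like_sites.tsv") as path:
        frame = read_tsv(path)
    annotations = [
        SiteAnnotation(
            name=row["site"], position=int(row["position"]),
            residue=row["residue"],
            context_motif=None if row["context_motif"] in ("-", "") else row["context_motif"],
            context_offset=int(row["context_offset"]),
        )
        for _, row in frame.iterrows()
    ]
    return record, annotations


def _column_map(alignment: Alignment) -> dict[int, int | None]:
    """Map reference positions (row 0) to query positions (row 1)."""
    ref_row, query_row = alignment.rows
    mapping: dict[int, int | None] = {}
    ref_pos = query_pos = 0
    for ref_ch, query_ch in zip(ref_row, query_row):
        if ref_ch != "-":
            ref_pos += 1
        if query_ch != "-":
            query_pos += 1
        if ref_ch != "-":
            mapping[ref_pos] = query_pos if query_ch != "-" else None
    return mapping


def locate_sites(query: ProteinRecord,
                 annotated_reference: ProteinRecord,
                 annotations: Iterable[SiteAnnotation]) -> ActiveSiteProfile:
    """Transfer annotated reference sites to the query by pairwise alignment.

    A site maps to the query residue aligned to the annotated reference
    column; sites aligned to a gap are absent.  The local motif context
    (dyad His inside LHS, Asn inside PNV, plant-type Ile inside PIx) is
    verified on the query and recorded under ``context_mismatch`` when it
    does not hold.
    """
    annotations = list(annotations)
    if not annotations:
        raise ValueError(f"reference {annotated_reference.id!r} lacks annotations")
    alignment, _ = pairwise_align(
        ProteinRecord("__reference__", annotated_reference.residues),
        ProteinRecord("__query__", query.residues))
    mapping = _column_map(alignment)

    positions: dict[str, int | None] = {}
    residues: dict[str, str] = {}
    mismatches: set[str] = set()
    for ann in annotations:
        pos = mapping.get(ann.position)
        positions[ann.name] = pos
        if pos is None:
            continue
        residues[ann.name] = query.residues[pos - 1]
        if ann.context_motif:
            definition = BUILTIN_MOTIFS[ann.context_motif]
            start = pos - ann.context_offset + 1
            window = query.residues[start - 1:start - 1 + len(definition)]
            if not definition.matches(window):
                mismatches.add(ann.name)

    plant = positions.get("plant_type_ile")
    bacterial = positions.get("bacterial_type_ile")
    if plant is not None:
        bacterial = plant - 4
        residues.setdefault("bacterial_type_ile",
                            query.residues[bacterial - 1] if bacterial >= 1 else "")
    return ActiveSiteProfile(
        dyad_his=positions.get("dyad_his"),
        dyad_asn=positions.get("dyad_asn"),
        plant_type_ile=plant,
        bacterial_type_position=bacterial,
        residue_states=dict(residues),
        context_mismatch=frozenset(mismatches),
    )


class MutationEffect(str, Enum):
    """Site-level mutation classes covered by the product rule table."""

    CLASS_I_KNOCKOUT = "CLASS_I_KNOCKOUT"   # first D of DDxxD -> A
    DYAD_HIS_ALA = "DYAD_HIS_ALA"
    DYAD_ASN_ALA = "DYAD_ASN_ALA"
    BACTERIAL_ILE_THR = "BACTERIAL_ILE_THR"
    PLANT_ILE_THR = "PLANT_ILE_THR"


class Product(str, Enum):
    ENT_CPP = "ent-CPP"
    ENT_KAURENE = "ent-kaurene"
    ENT_LPP = "ent-LPP"
    ENT_EPI_MANOYL_OXIDE = "ent-13-epi-manoyl oxide"
    ENT_PIMARADIENE = "ent-pimara-8(14),15-diene"
    HYDROXY_ENT_PIMARENE = "8alpha-hydroxy-ent-pimar-15-ene"
    NONE = "none"


@dataclass(frozen=True)
class ProductPrediction:
    products: tuple[Product, ...]   # major product first
    rule: str
    no_rule: bool = False


def predict_product(profile: ActiveSiteProfile, motif_status: MotifStatus,
                    mutations: Iterable[MutationEffect] = ()) -> ProductPrediction:
    """Predict the ordered product list for a CPS–KS-lineage enzyme.

    Requires a Class II-intact protein.  The shipped rules encode the
    observed outcomes: wild type makes ent-kaurene; the Class I knockout
    stalls at ent-CPP; dyad substitutions divert the Class II reaction to
    the hydroxylated ent-LPP route (ent-13-epi-manoyl oxide after the Class
    I step, ent-LPP itself when Class I is also knocked out; the Asn
    substitution is leaky and retains some ent-kaurene); threonine at the
    bacterial-type key position short-circuits the Class I cascade to
    ent-pimara-8(14),15-diene, and at the plant-type Ile to mostly
    8α-hydroxy-ent-pimar-15-ene with residual ent-kaurene.  Conditions are
    mutually exclusive; inputs matching no rule return ``none`` flagged.
    """
    if motif_status.classII is not ClassIIStatus.INTACT:
        raise ValueError("product rules are defined for Class II-intact "
                         "(CPS-KS lineage) proteins only")
    muts = frozenset(mutations)
    ko = MutationEffect.CLASS_I_KNOCKOUT in muts
    his = MutationEffect.DYAD_HIS_ALA in muts
    asn = MutationEffect.DYAD_ASN_ALA in muts
    bact = MutationEffect.BACTERIAL_ILE_THR in muts
    plant = MutationEffect.PLANT_ILE_THR in muts
    intact = motif_status.classI is ClassIStatus.INTACT

    if not muts and intact:
        return ProductPrediction((Product.ENT_KAURENE,), "wild_type")
    if ko and not (his or asn or bact or plant):
        return ProductPrediction((Product.ENT_CPP,), "class_i_knockout")
    if his and intact and not (ko or asn or bact or plant):
        return ProductPrediction((Product.ENT_EPI_MANOYL_OXIDE,), "dyad_his_ala")
    if asn and intact and not (ko or his or bact or plant):
        return ProductPrediction(
            (Product.ENT_EPI_MANOYL_OXIDE, Product.ENT_KAURENE), "dyad_asn_ala")
    if (his or asn) and ko and not (bact or plant):
        return ProductPrediction((Product.ENT_LPP,), "dyad_plus_knockout")
    if bact and intact and not (ko or his or asn or plant):
        return ProductPrediction((Product.ENT_PIMARADIENE,), "bacterial_ile_thr")
    if plant and intact and not (ko or his or asn or bact):
        return ProductPrediction(
            (Product.HYDROXY_ENT_PIMARENE, Product.ENT_KAURENE), "plant_ile_thr")
    return ProductPrediction((Product.NONE,), "no_rule", no_rule=True)
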