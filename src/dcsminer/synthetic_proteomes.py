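"""Labeled synthetic proteomes with planted domain architectures.

The generator emulates the protein classes a bacterial genome-mining screen
for fused diterpene cyclase/synthases must separate:

* ``DCS_INTACT``  — γβα tridomain fusions with intact Class II (DxDD) and
  Class I (DDxxD + NSE) motifs,
* ``DCS_ABERRANT`` — fusions whose Class I motifs are the aberrant
  DDxxx(D/E) / NGxxSxxxE variants (predicted Class I inactive),
* ``TS_ONLY``     — α-domain-only terpene synthases,
* ``DTC_ONLY``    — γβ-didomain-only diterpene cyclases,
* ``SHC_DECOY``   — squalene–hopene-cyclase-like γβ proteins that share the
  DxDD motif but are otherwise unrelated to the DTC templates,
* ``BACKGROUND``  — motif-free random proteins.

Sequences are derived from three fixed packaged templates by seeded point
mutation of non-motif positions; planted motifs are mutation-locked so truth
labels stay valid.  Each class descends from its own class ancestor (mutated
at the full divergence rate) with instances mutated at half that rate, so
within-class sequences are more similar than between-class ones and
distance-based trees recover the planted classes as clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motif_engine import Region
from .seqio import AMINO_ACIDS, ProteinRecord, write_fasta, write_tsv

# Residues used for template backbones, linkers and substitutions.  D, H and
# N are excluded so no built-in aspartate/dyad motif can arise by chance
# outside the planted positions.
_BASIS = "ACEFGIKLMPQRSTVWY"

# Concrete planted motif instances (wildcards filled with basis residues).
_DXDD_SEQ = "DVDD"
_DDXXD_SEQ = "DDTAD"
_NSE_SEQ = "NDTASVAVE"
_ABERRANT_DD_SEQ = "DDTAVD"
_NSE_VARIANT_SEQ = "NGTASVAVE"
_LHS_SEQ = "LHS"
_PNV_SEQ = "PNV"

ALPHA_LEN = 300
GB_LEN = 500
SHC_LEN = 500

# 1-based positions of planted motifs within each template part.
ALPHA_DDXXD_POS = 60
ALPHA_NSE_POS = 200          # start-to-start spacing DDxxD -> NSE = 140
ALPHA_BACT_ILE_POS = 250     # bacterial-type key residue
ALPHA_PIX_POS = 253          # PIx context; plant-type Ile at 254 = 250 + 4
GB_LHS_POS = 110
GB_PNV_POS = 180
GB_DXDD_POS = 380
SHC_DXDD_POS = 380


def _basis_string(rng: np.random.Generator, n: int) -> list[str]:
    return [
        _BASIS[i] for i in rng.integers(0, len(_BASIS), size=n)
    ]


def _plant(seq: list[str], start: int, motif: str) -> None:
    seq[start - 1:start - 1 + len(motif)] = list(motif)


def _build_alpha(basis: list[str], dd: str = "canonical", nse: str = "canonical") -> str:
    seq = list(basis)
    _plant(seq, ALPHA_DDXXD_POS, _DDXXD_SEQ if dd == "canonical" else _ABERRANT_DD_SEQ)
    if dd == "canonical":
        seq[ALPHA_DDXXD_POS + len(_DDXXD_SEQ) - 1] = "A"  # guard: no D/E follows
    _plant(seq, ALPHA_NSE_POS, _NSE_SEQ if nse == "canonical" else _NSE_VARIANT_SEQ)
    seq[ALPHA_BACT_ILE_POS - 1] = "I"
    _plant(seq, ALPHA_PIX_POS, "PIA")
    return "".join(seq)


def _build_gb(basis: list[str]) -> str:
    seq = list(basis)
    _plant(seq, GB_LHS_POS, _LHS_SEQ)
    _plant(seq, GB_PNV_POS, _PNV_SEQ)
    _plant(seq, GB_DXDD_POS, _DXDD_SEQ)
    return "".join(seq)


def _template_rng(stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64([20240803, stream]))


_ALPHA_BASIS = _basis_string(_template_rng(1), ALPHA_LEN)
_GB_BASIS = _basis_string(_template_rng(2), GB_LEN)
_SHC_BASIS = _basis_string(_template_rng(3), SHC_LEN)

#: fixed packaged templates
ALPHA_TEMPLATE = _build_alpha(_ALPHA_BASIS)
ALPHA_TEMPLATE_ABERRANT = _build_alpha(_ALPHA_BASIS, dd="aberrant", nse="variant")
ALPHA_TEMPLATE_ABERRANT_DD_ONLY = _build_alpha(_ALPHA_BASIS, dd="aberrant", nse="canonical")
GB_TEMPLATE = _build_gb(_GB_BASIS)
SHC_TEMPLATE = "".join(
    list(_SHC_BASIS[:SHC_DXDD_POS - 1]) + list(_DXDD_SEQ)
    + _SHC_BASIS[SHC_DXDD_POS - 1 + len(_DXDD_SEQ):]
)

_ALPHA_FROZEN = frozenset(
    set(range(ALPHA_DDXXD_POS, ALPHA_DDXXD_POS + 6))
    | set(range(ALPHA_NSE_POS, ALPHA_NSE_POS + 9))
    | {ALPHA_BACT_ILE_POS, ALPHA_PIX_POS, ALPHA_PIX_POS + 1, ALPHA_PIX_POS + 2}
)
_GB_FROZEN = frozenset(
    set(range(GB_LHS_POS, GB_LHS_POS + 3))
    | set(range(GB_PNV_POS, GB_PNV_POS + 3))
    | set(range(GB_DXDD_POS, GB_DXDD_POS + 4))
)
_SHC_FROZEN = frozenset(range(SHC_DXDD_POS, SHC_DXDD_POS + 4))

CLASS_NAMES = ("DCS_INTACT", "DCS_ABERRANT", "TS_ONLY", "DTC_ONLY",
               "SHC_DECOY", "BACKGROUND")


@dataclass(frozen=True)
class SyntheticSpec:
    """Composition and divergence of a synthetic proteome.

    The default composition is the canonical 50-protein screen used
    throughout the test suite: 5 intact + 2 aberrant fusions, 10 α-only TSs,
    10 γβ-only DTCs, 3 SHC decoys and 20 background proteins.
    """

    n_dcs_intact: int = 5
    n_dcs_aberrant: int = 2
    n_ts_only: int = 10
    n_dtc_only: int = 10
    n_shc_decoy: int = 3
    n_background: int = 20
    background_length_range: tuple[int, int] = (150, 450)
    template_identity: float = 0.9
    linker_length_range: tuple[int, int] = (5, 25)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_dcs_intact, self.n_dcs_aberrant, self.n_ts_only,
                  self.n_dtc_only, self.n_shc_decoy, self.n_background)
        if any(c < 0 for c in counts):
            raise ValueError("class counts must be non-negative")
        if not (0.0 < self.template_identity <= 1.0):
            raise ValueError("template_identity must be in (0, 1]")
        for lo, hi in (self.background_length_range, self.linker_length_range):
            if lo > hi or lo < 0:
                raise ValueError("ranges must be ordered and non-negative")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one synthetic protein."""

    protein_id: str
    true_class: str
    intervals: Mapping[str, tuple[int, int]]
    motifs: Mapping[str, tuple[int, ...]]


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            frozen: frozenset[int]) -> str:
    """Substitute non-frozen positions with probability *rate*; replacements
    are drawn from the basis alphabet and always differ from the original."""
    if rate <= 0.0:
        return seq
    out = list(seq)
    draws = rng.random(len(out))
    for idx in np.flatnonzero(draws < rate):
        pos = int(idx) + 1
        if pos in frozen:
            continue
        choices = _BASIS.replace(out[idx], "")
        out[idx] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def _alpha_motifs(offset: int, variant: str) -> dict[str, tuple[int, ...]]:
    if variant == "intact":
        return {"DDxxD": (offset + ALPHA_DDXXD_POS,),
                "NSE": (offset + ALPHA_NSE_POS,),
                "PIx": (offset + ALPHA_PIX_POS,)}
    if variant == "aberrant_dd_only":
        return {"ABERRANT_DD": (offset + ALPHA_DDXXD_POS,),
                "NSE": (offset + ALPHA_NSE_POS,),
                "PIx": (offset + ALPHA_PIX_POS,)}
    return {"ABERRANT_DD": (offset + ALPHA_DDXXD_POS,),
            "NSE_VARIANT": (offset + ALPHA_NSE_POS,),
            "PIx": (offset + ALPHA_PIX_POS,)}


def _gb_motifs() -> dict[str, tuple[int, ...]]:
    return {"LHS": (GB_LHS_POS,), "PNV": (GB_PNV_POS,), "DxDD": (GB_DXDD_POS,)}


def generate_proteome(spec: SyntheticSpec) -> tuple[list[ProteinRecord], list[TruthRecord]]:
    """Generate a labeled synthetic proteome. Deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    rate = 1.0 - spec.template_identity
    half = rate / 2.0

    # Class ancestors, drawn in a fixed order so output is reproducible.
    anc = {
        "DCSI_GB": _mutate(GB_TEMPLATE, rate, rng, _GB_FROZEN),
        "DCSI_ALPHA": _mutate(ALPHA_TEMPLATE, rate, rng, _ALPHA_FROZEN),
        "DCSA_GB": _mutate(GB_TEMPLATE, rate, rng, _GB_FROZEN),
        "DCSA_ALPHA": _mutate(ALPHA_TEMPLATE_ABERRANT, rate, rng, _ALPHA_FROZEN),
        "TS_ALPHA": _mutate(ALPHA_TEMPLATE, rate, rng, _ALPHA_FROZEN),
        "DTC_GB": _mutate(GB_TEMPLATE, rate, rng, _GB_FROZEN),
        "SHC": _mutate(SHC_TEMPLATE, rate, rng, _SHC_FROZEN),
    }

    records: list[ProteinRecord] = []
    truths: list[TruthRecord] = []
    species_no = 0

    def species() -> str:
        nonlocal species_no
        species_no += 1
        return f"sp{species_no:04d}"

    def add(rec: ProteinRecord, truth: TruthRecord) -> None:
        records.append(rec)
        truths.append(truth)

    lo_link, hi_link = spec.linker_length_range
    for variant, count, prefix, cls in (
        ("intact", spec.n_dcs_intact, "DCSI", "DCS_INTACT"),
        ("aberrant", spec.n_dcs_aberrant, "DCSA", "DCS_ABERRANT"),
    ):
        for i in range(count):
            gb = _mutate(anc[f"{prefix}_GB"], half, rng, _GB_FROZEN)
            alpha = _mutate(anc[f"{prefix}_ALPHA"], half, rng, _ALPHA_FROZEN)
            link_len = int(rng.integers(lo_link, hi_link + 1))
            linker = "".join(_basis_string(rng, link_len))
            seq = gb + linker + alpha
            offset = GB_LEN + link_len
            pid = f"{prefix}_{i + 1:03d}"
            motifs = dict(_gb_motifs())
            motifs.update(_alpha_motifs(offset, variant))
            add(ProteinRecord(pid, seq, species=species()),
                TruthRecord(pid, cls,
                            {"GB": (1, GB_LEN), "ALPHA": (offset + 1, len(seq))},
                            motifs))

    for i in range(spec.n_ts_only):
        seq = _mutate(anc["TS_ALPHA"], half, rng, _ALPHA_FROZEN)
        pid = f"TS_{i + 1:03d}"
        add(ProteinRecord(pid, seq, species=species()),
            TruthRecord(pid, "TS_ONLY", {"ALPHA": (1, ALPHA_LEN)},
                        _alpha_motifs(0, "intact")))

    for i in range(spec.n_dtc_only):
        seq = _mutate(anc["DTC_GB"], half, rng, _GB_FROZEN)
        pid = f"DTC_{i + 1:03d}"
        add(ProteinRecord(pid, seq, species=species()),
            TruthRecord(pid, "DTC_ONLY", {"GB": (1, GB_LEN)}, _gb_motifs()))

    for i in range(spec.n_shc_decoy):
        seq = _mutate(anc["SHC"], half, rng, _SHC_FROZEN)
        pid = f"SHC_{i + 1:03d}"
        add(ProteinRecord(pid, seq, species=species()),
            TruthRecord(pid, "SHC_DECOY", {"SHC": (1, SHC_LEN)},
                        {"DxDD": (SHC_DXDD_POS,)}))

    lo_bg, hi_bg = spec.background_length_range
    for i in range(spec.n_background):
        length = int(rng.integers(lo_bg, hi_bg + 1))
        seq = "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, size=length))
        pid = f"BG_{i + 1:03d}"
        add(ProteinRecord(pid, seq, species=species()),
            TruthRecord(pid, "BACKGROUND", {}, {}))

    return records, truths


EXPECTED_CALL = {
    "DCS_INTACT": "DCS_CANDIDATE",
    "DCS_ABERRANT": "DCS_CANDIDATE",
    "TS_ONLY": "TS_ONLY",
    "DTC_ONLY": "DTC_ONLY",
    "SHC_DECOY": "SHC_LIKE",
    "BACKGROUND": "NONE",
}


@dataclass(frozen=True)
class RecoveryTable:
    """Per-class recovery of the planted architecture plus confusion counts."""

    per_class: pd.DataFrame
    confusion: pd.DataFrame


def evaluate_screen(calls: Sequence, truths: Sequence[TruthRecord]) -> RecoveryTable:
    """Score architecture calls against planted truth.

    Sensitivity and precision are reported for the DCS candidate pool
    (DCS_INTACT ∪ DCS_ABERRANT vs. the DCS_CANDIDATE call), TS_ONLY and
    DTC_ONLY; undefined precision (no positive calls) is reported as NaN.
    The protein-id universes of calls and truth must coincide.
    """
    call_by_id = {c.protein_id: c.call for c in calls}
    truth_by_id = {t.protein_id: t.true_class for t in truths}
    if set(call_by_id) != set(truth_by_id):
        diff = sorted(set(call_by_id) ^ set(truth_by_id))
        raise ValueError(f"call/truth id mismatch: {diff}")

    confusion = pd.crosstab(
        pd.Series({i: truth_by_id[i] for i in truth_by_id}, name="true_class"),
        pd.Series({i: str(call_by_id[i]) for i in call_by_id}, name="call"),
    )

    groups = {
        "DCS_CANDIDATE": ({"DCS_INTACT", "DCS_ABERRANT"}, "DCS_CANDIDATE"),
        "TS_ONLY": ({"TS_ONLY"}, "TS_ONLY"),
        "DTC_ONLY": ({"DTC_ONLY"}, "DTC_ONLY"),
    }
    rows = []
    for name, (truth_classes, call_name) in groups.items():
        truth_ids = {i for i, c in truth_by_id.items() if c in truth_classes}
        called_ids = {i for i, c in call_by_id.items() if str(c) == call_name}
        tp = len(truth_ids & called_ids)
        sens = tp / len(truth_ids) if truth_ids else np.nan
        prec = tp / len(called_ids) if called_ids else np.nan
        rows.append({"group": name, "tp": tp, "fn": len(truth_ids) - tp,
                     "fp": len(called_ids) - tp, "sensitivity": sens,
                     "precision": prec})
    return RecoveryTable(per_class=pd.DataFrame(rows), confusion=confusion)


def write_truth_tsv(truths: Iterable[TruthRecord], path: str | Path) -> None:
    rows = []
    for t in truths:
        rows.append({
            "protein_id": t.protein_id,
            "true_class": t.true_class,
            "intervals": ";".join(f"{k}:{s}-{e}" for k, (s, e) in sorted(t.intervals.items())),
            "motifs": ";".join(f"{k}@{','.join(map(str, v))}"
                               for k, v in sorted(t.motifs.items())),
        })
    write_tsv(pd.DataFrame(rows, columns=["protein_id", "true_class",
                                          "intervals", "motifs"]), path)


def dcs_motif_panel(seed: int = 7, identity: float = 0.95,
                    ) -> tuple[list[ProteinRecord], dict[str, dict[Region, tuple[int, int]]]]:
    """Synthetic five-protein DCS panel mirroring the motif-status spectrum of
    the characterized bacterial fusion proteins: three members with intact
    canonical Class I motifs, one with an aberrantly spaced DDxxx(D/E) motif
    only, and one with both the aberrant DDxxx(D/E) and the NGxxSxxxE
    variant.  All five carry the Class II DxDD motif in the γβ region.

    Returns the records plus per-protein γβ/α region intervals.
    """
    rng = np.random.default_rng(seed)
    half = (1.0 - identity) / 2.0
    variants = [
        ("synDCS_A", "intact"),
        ("synDCS_B", "intact"),
        ("synDCS_C", "intact"),
        ("synDCS_D", "aberrant_dd_only"),
        ("synDCS_E", "aberrant"),
    ]
    alpha_templates = {
        "intact": ALPHA_TEMPLATE,
        "aberrant_dd_only": ALPHA_TEMPLATE_ABERRANT_DD_ONLY,
        "aberrant": ALPHA_TEMPLATE_ABERRANT,
    }
    records = []
    regions: dict[str, dict[Region, tuple[int, int]]] = {}
    linker = 10
    for pid, variant in variants:
        gb = _mutate(GB_TEMPLATE, half, rng, _GB_FROZEN)
        alpha = _mutate(alpha_templates[variant], half, rng, _ALPHA_FROZEN)
        seq = gb + "".join(_basis_string(rng, linker)) + alpha
        records.append(ProteinRecord(pid, seq, description="synthetic DCS panel member"))
        regions[pid] = {Region.GB_REGION: (1, GB_LEN),
                        Region.ALPHA_REGION: (GB_LEN + linker + 1, len(seq))}
    return records, regions


# Annotated reference positions of the synthetic CseDCS-like fixture.
REFERENCE_SITES = {
    "dyad_his": (187, "H", "LHS", 2),
    "dyad_asn": (253, "N", "PNV", 2),
    "bacterial_type_ile": (726, "I", None, 0),
    "plant_type_ile": (730, "I", "PIx", 2),
}
REFERENCE_GB_END = 540
REFERENCE_LEN = 840
REFERENCE_DDXXD_POS = 610
REFERENCE_NSE_POS = 750
REFERENCE_DXDD_POS = 380


def csedcs_like_reference() -> ProteinRecord:
    """Deterministic synthetic stand-in for an annotated bifunctional
    CPS–KS reference, with the His-Asn dyad at 187/253 (inside LHS/PNV), the
    Class I motifs at 610/750 and the key isoleucines at 726 (bacterial-type
    position) and 730 (plant-type, inside PIx)."""
    rng = _template_rng(4)
    seq = _basis_string(rng, REFERENCE_LEN)
    _plant(seq, REFERENCE_SITES["dyad_his"][0] - 1, _LHS_SEQ)      # LHS at 186
    _plant(seq, REFERENCE_SITES["dyad_asn"][0] - 1, _PNV_SEQ)      # PNV at 252
    _plant(seq, REFERENCE_DXDD_POS, _DXDD_SEQ)
    _plant(seq, REFERENCE_DDXXD_POS, _DDXXD_SEQ)
    seq[REFERENCE_DDXXD_POS + len(_DDXXD_SEQ) - 1] = "A"
    _plant(seq, REFERENCE_NSE_POS, _NSE_SEQ)
    seq[726 - 1] = "I"
    _plant(seq, 729, "PIA")                                        # P729 I730
    return ProteinRecord("synCseDCS_like", "".join(seq),
                         description="synthetic annotated CPS-KS reference")


def write_reference_fixture(fasta_path: str | Path, sites_path: str | Path) -> None:
    """Write the synthetic annotated reference as FASTA plus sidecar TSV."""
    write_fasta([csedcs_like_reference()], fasta_path)
    rows = [{"site": name, "position": pos, "residue": res,
             "context_motif": motif or "-", "context_offset": off}
            for name, (pos, res, motif, off) in REFERENCE_SITES.items()]
    write_tsv(pd.DataFrame(rows), sites_path)
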