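"""Per-protein architecture calls: the central fusion screen.

A protein carrying a γβ-didomain hit N-terminal to an α-domain hit has the
γβα order diagnostic of fused bifunctional diterpene cyclase/synthases and
is called a DCS candidate; the candidate is predicted bifunctional only when
both the Class II (DxDD) and Class I (DDxxD + NSE) motif sets are intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .domain_detection import DomainClass, DomainHit
from .motif_engine import ClassIStatus, ClassIIStatus, MotifStatus
from .seqio import ProteinRecord


class Call(str, Enum):
    DCS_CANDIDATE = "DCS_CANDIDATE"
    DCS_ATYPICAL_ORDER = "DCS_ATYPICAL_ORDER"
    TS_ONLY = "TS_ONLY"
    DTC_ONLY = "DTC_ONLY"
    SHC_LIKE = "SHC_LIKE"
    NONE = "NONE"

    def __str__(self) -> str:  # report-friendly
        return self.value


@dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    hits: tuple[DomainHit, ...]
    call: Call
    motif_status: MotifStatus
    predicted_bifunctional: bool

    def gb_hit(self) -> DomainHit | None:
        """Most N-terminal γβ hit (the one used for the order test)."""
        gb = [h for h in self.hits if h.domain_class is DomainClass.GB_DTC]
        return min(gb, key=lambda h: h.start) if gb else None

    def alpha_hit(self) -> DomainHit | None:
        """Most C-terminal α hit (the one used for the order test)."""
        alpha = [h for h in self.hits if h.domain_class is DomainClass.ALPHA_TS]
        return max(alpha, key=lambda h: h.end) if alpha else None


def call_architecture(record: ProteinRecord, hits: Sequence[DomainHit],
                      motif_status: MotifStatus,
                      shc_flagged: bool = False) -> ArchitectureCall:
    """Assign the architecture call for one protein.

    Both domain classes with γβ before α (most N-terminal γβ hit ending
    before the most C-terminal α hit starts) gives DCS_CANDIDATE; both
    classes in any other arrangement gives DCS_ATYPICAL_ORDER; α only gives
    TS_ONLY; γβ only gives DTC_ONLY, or SHC_LIKE when the γβ region is
    SHC-flagged; no hits gives NONE.
    """
    for hit in hits:
        if hit.protein_id != record.id:
            raise ValueError(
                f"hit for {hit.protein_id!r} passed with record {record.id!r}")
    ordered = tuple(sorted(hits, key=lambda h: (h.start, h.domain_class.value)))
    classes = {h.domain_class for h in ordered}
    has_alpha = DomainClass.ALPHA_TS in classes
    has_gb = DomainClass.GB_DTC in classes
    gb_like = has_gb or DomainClass.SHC_LIKE in classes
    shc = shc_flagged or (DomainClass.SHC_LIKE in classes and not has_gb)

    if has_alpha and has_gb and not shc:
        gb = min((h for h in ordered if h.domain_class is DomainClass.GB_DTC),
                 key=lambda h: h.start)
        alpha = max((h for h in ordered if h.domain_class is DomainClass.ALPHA_TS),
                    key=lambda h: h.end)
        call = Call.DCS_CANDIDATE if gb.end < alpha.start else Call.DCS_ATYPICAL_ORDER
    elif has_alpha and not gb_like:
        call = Call.TS_ONLY
    elif gb_like and not has_alpha:
        call = Call.SHC_LIKE if shc else Call.DTC_ONLY
    elif gb_like and has_alpha:  # SHC-flagged γβ plus α evidence
        call = Call.SHC_LIKE
    else:
        call = Call.NONE

    predicted = (call is Call.DCS_CANDIDATE
                 and motif_status.classI is ClassIStatus.INTACT
                 and motif_status.classII is ClassIIStatus.INTACT)
    return ArchitectureCall(protein_id=record.id, hits=ordered, call=call,
                            motif_status=motif_status,
                            predicted_bifunctional=predicted)


_TRACK_WIDTH = 60
_TRACK_CHARS = {DomainClass.GB_DTC: "B", DomainClass.ALPHA_TS: "A",
                DomainClass.SHC_LIKE: "S"}


def _ascii_track(call: ArchitectureCall, length: int) -> str:
    track = ["."] * _TRACK_WIDTH
    scale = _TRACK_WIDTH / max(length, 1)
    for hit in call.hits:
        lo = int((hit.start - 1) * scale)
        hi = max(lo + 1, int(hit.end * scale))
        for i in range(lo, min(hi, _TRACK_WIDTH)):
            track[i] = _TRACK_CHARS[hit.domain_class]
    for hit in call.motif_status.supporting_hits:
        pos = min(int((hit.start - 1) * scale), _TRACK_WIDTH - 1)
        track[pos] = "*"
    return "".join(track)


def _interval_text(call: ArchitectureCall, domain_class: DomainClass) -> str:
    spans = [f"{h.start}-{h.end}" for h in call.hits
             if h.domain_class is domain_class]
    return ";".join(spans)


REPORT_COLUMNS = ["protein_id", "call", "gb_intervals", "alpha_intervals",
                  "shc_intervals", "classII", "classI",
                  "predicted_bifunctional"]


def architecture_table(calls: Iterable[ArchitectureCall]) -> pd.DataFrame:
    """One row per protein, sorted by id, with intervals and motif statuses."""
    rows = []
    for call in sorted(calls, key=lambda c: c.protein_id):
        rows.append({
            "protein_id": call.protein_id,
            "call": call.call.value,
            "gb_intervals": _interval_text(call, DomainClass.GB_DTC),
            "alpha_intervals": _interval_text(call, DomainClass.ALPHA_TS),
            "shc_intervals": _interval_text(call, DomainClass.SHC_LIKE),
            "classII": call.motif_status.classII.value,
            "classI": call.motif_status.classI.value,
            "predicted_bifunctional": call.predicted_bifunctional,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def render_architecture(calls: Sequence[ArchitectureCall],
                        lengths: Mapping[str, int] | None = None,
                        ) -> tuple[str, pd.DataFrame]:
    """Render an ASCII architecture report plus the per-protein TSV table.

    Domain tracks use ``B`` for γβ, ``A`` for α, ``S`` for SHC-like regions
    and ``*`` for motif positions.  *lengths* maps protein ids to sequence
    lengths; when missing, the furthest hit end is used.
    """
    lengths = lengths or {}
    lines = []
    for call in sorted(calls, key=lambda c: c.protein_id):
        length = lengths.get(call.protein_id,
                             max((h.end for h in call.hits), default=1))
        lines.append(f"{call.protein_id:<20} {call.call.value:<18} "
                     f"{_ascii_track(call, length)}")
    return "\n".join(lines), architecture_table(calls)
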