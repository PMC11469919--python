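"""Degenerate catalytic-motif compilation, scanning and Class I/II status calls.

Diterpene cyclases (Class II) carry the DxDD catalytic acid motif in their
γβ-didomain; terpene synthases (Class I) carry the DDxxD and
(N/D)Dxx(S/T/G)xxx(E/D) ("NSE") magnesium-binding motifs in the α-domain.
Fused bifunctional enzymes carry all three, and aberrant variants of the
Class I pair (DDxxx(D/E) spacing, NGxxSxxxE) mark candidates that are
unlikely to retain Class I activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .seqio import AMINO_ACIDS, ProteinRecord


class Region(str, Enum):
    """Which part of the protein a motif is constrained to."""

    GB_REGION = "GB_REGION"
    ALPHA_REGION = "ALPHA_REGION"
    ANY = "ANY"


@dataclass(frozen=True)
class MotifDefinition:
    """A degenerate motif: per-position residue constraints.

    ``positions`` holds, for each motif position, either ``None`` (wildcard)
    or a frozenset of allowed residues.  A wildcard matches any residue
    including X; an exact position does not match X.
    """

    name: str
    positions: tuple[frozenset[str] | None, ...]
    region_constraint: Region = Region.ANY

    def __post_init__(self) -> None:
        if len(self.positions) < 3:
            raise ValueError(f"motif {self.name}: length must be >= 3")
        for pos in self.positions:
            if pos is not None and (not pos or not pos <= set(AMINO_ACIDS)):
                raise ValueError(f"motif {self.name}: bad residue set {pos}")

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, window: str) -> bool:
        if len(window) != len(self.positions):
            return False
        for ch, allowed in zip(window, self.positions):
            if allowed is not None and ch not in allowed:
                return False
        return True


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int  # 1-based
    matched: str


def compile_motif(pattern_text: str, name: str | None = None,
                  region: Region = Region.ANY) -> MotifDefinition:
    """Compile motif notation into a :class:`MotifDefinition`.

    Grammar: an uppercase letter is an exact residue, ``x`` is a wildcard and
    ``(A/B/C)`` is a set of alternatives.  Malformed patterns raise
    ``ValueError`` with the offending column.
    """
    if not pattern_text:
        raise ValueError("empty motif pattern")
    positions: list[frozenset[str] | None] = []
    i = 0
    n = len(pattern_text)
    while i < n:
        ch = pattern_text[i]
        if ch == "x":
            positions.append(None)
            i += 1
        elif ch == "(":
            j = pattern_text.find(")", i)
            if j < 0:
                raise ValueError(f"column {i + 1}: unbalanced parenthesis")
            alts = pattern_text[i + 1:j].split("/")
            residues = frozenset(alts)
            if not alts or not all(a in AMINO_ACIDS and len(a) == 1 for a in alts):
                raise ValueError(f"column {i + 1}: bad alternative group "
                                 f"{pattern_text[i:j + 1]!r}")
            positions.append(residues)
            i = j + 1
        elif ch in AMINO_ACIDS:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise ValueError(f"column {i + 1}: illegal character {ch!r}")
    return MotifDefinition(name=name or pattern_text, positions=tuple(positions),
                           region_constraint=region)


# Built-in motif set.  The Class II DxDD acid sits in the γβ-didomain, the
# Class I DDxxD/NSE pair in the α-domain; LHS and PNV carry the His-Asn dyad
# of the Class II active site (γ-domain) and PIx the plant-type key Ile of
# kaurene synthases.
BUILTIN_MOTIFS: dict[str, MotifDefinition] = {
    "DxDD": compile_motif("DxDD", "DxDD", Region.GB_REGION),
    "DDxxD": compile_motif("DDxxD", "DDxxD", Region.ALPHA_REGION),
    "NSE": compile_motif("(N/D)Dxx(S/T/G)xxx(E/D)", "NSE", Region.ALPHA_REGION),
    "ABERRANT_DD": compile_motif("DDxxx(D/E)", "ABERRANT_DD", Region.ALPHA_REGION),
    "NSE_VARIANT": compile_motif("NGxxSxxxE", "NSE_VARIANT", Region.ALPHA_REGION),
    "LHS": compile_motif("LHS", "LHS", Region.GB_REGION),
    "PNV": compile_motif("PNV", "PNV", Region.GB_REGION),
    "PIx": compile_motif("PIx", "PIx", Region.ALPHA_REGION),
}


def default_regions(length: int) -> dict[Region, tuple[int, int]]:
    """Fallback region split when no domain hits are available: the N-terminal
    half is treated as the γβ region, the C-terminal half as the α region."""
    half = (length + 1) // 2
    return {Region.GB_REGION: (1, half),
            Region.ALPHA_REGION: (min(half + 1, length), length)}


def scan_motifs(record: ProteinRecord,
                definitions: Iterable[MotifDefinition] | None = None,
                region_intervals: Mapping[Region, tuple[int, int]] | None = None,
                ) -> list[MotifHit]:
    """Report every motif match whose full span lies inside its region.

    Overlapping matches are all reported, in ascending start order (ties
    broken by motif name).  ``region_intervals`` supplies the γβ and α
    intervals when domain hits are known; otherwise the sequence is split at
    its midpoint.
    """
    if definitions is None:
        definitions = BUILTIN_MOTIFS.values()
    seq = record.residues
    regions = dict(default_regions(len(seq)))
    if region_intervals:
        regions.update(region_intervals)
    hits: list[MotifHit] = []
    for definition in definitions:
        span = len(definition)
        if definition.region_constraint is Region.ANY:
            lo, hi = 1, len(seq)
        else:
            if definition.region_constraint not in regions:
                continue
            lo, hi = regions[definition.region_constraint]
        for start in range(lo, hi - span + 2):
            window = seq[start - 1:start - 1 + span]
            if definition.matches(window):
                hits.append(MotifHit(definition.name, start, window))
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


class ClassIIStatus(str, Enum):
    INTACT = "INTACT"
    ABSENT = "ABSENT"


class ClassIStatus(str, Enum):
    INTACT = "INTACT"
    ABERRANT = "ABERRANT"
    ABSENT = "ABSENT"


# Plausible DDxxD -> NSE start-to-start spacing for a single α-domain.
CLASSI_SPACING_WINDOW = (80, 220)


@dataclass(frozen=True)
class MotifStatus:
    classII: ClassIIStatus
    classI: ClassIStatus
    supporting_hits: tuple[MotifHit, ...] = ()


def classify_motif_status(hits: Sequence[MotifHit],
                          spacing_window: tuple[int, int] = CLASSI_SPACING_WINDOW,
                          ) -> MotifStatus:
    """Classify Class II / Class I motif status from one protein's motif hits.

    Class II is INTACT iff a DxDD hit is present (hits are assumed to have
    been scanned under region constraints, so DxDD hits already lie in the γβ
    region).  Class I is INTACT iff canonical DDxxD and NSE hits co-occur
    with DDxxD upstream and a start-to-start separation inside
    *spacing_window*; ABERRANT covers the aberrantly spaced DDxxx(D/E) and
    NGxxSxxxE variants as well as canonical pairs with out-of-window spacing.
    When both canonical and aberrant motifs occur, the canonical pair wins.
    """
    by_name: dict[str, list[MotifHit]] = {}
    for hit in hits:
        by_name.setdefault(hit.motif_name, []).append(hit)
    for name in by_name:
        by_name[name].sort(key=lambda h: h.start)

    class_ii = ClassIIStatus.INTACT if by_name.get("DxDD") else ClassIIStatus.ABSENT

    dd_hits = by_name.get("DDxxD", [])
    nse_hits = by_name.get("NSE", [])
    lo, hi = spacing_window
    intact = any(
        dd.start < nse.start and lo <= nse.start - dd.start <= hi
        for dd in dd_hits for nse in nse_hits
    )
    if intact:
        class_i = ClassIStatus.INTACT
    elif (by_name.get("ABERRANT_DD") or by_name.get("NSE_VARIANT")
          or (dd_hits and nse_hits)):
        class_i = ClassIStatus.ABERRANT
    else:
        class_i = ClassIStatus.ABSENT
    return MotifStatus(classII=class_ii, classI=class_i,
                       supporting_hits=tuple(sorted(hits, key=lambda h: (h.start, h.motif_name))))


def motifs_from_config(entries: Iterable[Mapping]) -> dict[str, MotifDefinition]:
    """Build an extended motif set from config ``motifs:`` entries
    (``name`` / ``pattern`` / ``region``)."""
    motifs = dict(BUILTIN_MOTIFS)
    for entry in entries:
        region = Region(entry.get("region", "ANY"))
        motifs[entry["name"]] = compile_motif(entry["pattern"], entry["name"], region)
    return motifs
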