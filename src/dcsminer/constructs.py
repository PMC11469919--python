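"""Domain splitting and anchored in-silico mutagenesis of fusion candidates.

A DCS candidate can be split into an independently testable N-terminal
γβ-didomain (diterpene cyclase) and C-terminal α-domain (terpene synthase)
construct.  Mutations are anchored to catalytic motifs (e.g. the first
aspartate of DDxxD to alanine — the Class I knockout) so the same mutation
recipe transfers across homologs; labels use the absolute 1-based position
of the replaced residue, D610A style.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .fusion_architecture import ArchitectureCall, Call
from .motif_engine import (BUILTIN_MOTIFS, MotifDefinition, Region,
                           scan_motifs)
from .seqio import ProteinRecord


class Part(str, Enum):
    NTERM_GB = "NTERM_GB"
    CTERM_ALPHA = "CTERM_ALPHA"


@dataclass(frozen=True)
class SplitConstruct:
    parent_id: str
    part: Part
    boundary: int  # last residue of the N-terminal part
    residues: str

    @property
    def id(self) -> str:
        suffix = "GB" if self.part is Part.NTERM_GB else "ALPHA"
        return f"{self.parent_id}:{suffix}"

    def as_record(self, species: str = "") -> ProteinRecord:
        return ProteinRecord(self.id, self.residues, species=species,
                             description=f"split of {self.parent_id} at {self.boundary}")


# Slack allowed for explicit boundaries upstream of the γβ hit end.
_EXPLICIT_SLACK = 20


def split_dcs(record: ProteinRecord, architecture_call: ArchitectureCall,
              boundary_rule: str = "GB_END") -> tuple[SplitConstruct, SplitConstruct]:
    """Split a DCS candidate into γβ and α constructs.

    ``boundary_rule`` is ``GB_END`` (default: last residue of the γβ hit),
    ``MIDLINKER`` (midpoint of the inter-domain gap) or ``EXPLICIT:n``.
    Explicit boundaries outside ``[γβ end − 20, α start − 1]`` are rejected.
    The two constructs concatenate back to the parent for every rule.
    """
    if architecture_call.call is not Call.DCS_CANDIDATE:
        raise ValueError(f"{record.id}: split requires a DCS_CANDIDATE call, "
                         f"got {architecture_call.call.value}")
    gb = architecture_call.gb_hit()
    alpha = architecture_call.alpha_hit()
    assert gb is not None and alpha is not None

    if boundary_rule == "GB_END":
        boundary = gb.end
    elif boundary_rule == "MIDLINKER":
        boundary = (gb.end + alpha.start - 1) // 2
    elif boundary_rule.startswith("EXPLICIT:"):
        boundary = int(boundary_rule.split(":", 1)[1])
        if not (gb.end - _EXPLICIT_SLACK <= boundary <= alpha.start - 1):
            raise ValueError(
                f"{record.id}: explicit boundary {boundary} outside "
                f"[{gb.end - _EXPLICIT_SLACK}, {alpha.start - 1}]")
    else:
        raise ValueError(f"unknown boundary rule {boundary_rule!r}")

    nterm = SplitConstruct(record.id, Part.NTERM_GB, boundary,
                           record.residues[:boundary])
    cterm = SplitConstruct(record.id, Part.CTERM_ALPHA, boundary,
                           record.residues[boundary:])
    return nterm, cterm


@dataclass(frozen=True)
class AnchoredMutation:
    """A point mutation anchored to a motif occurrence.

    ``occurrence`` indexes the motif's region-constrained hits (1-based, in
    sequence order); ``offset`` is the 1-based position within the motif.
    """

    anchor_motif: str
    occurrence: int
    offset: int
    replacement: str

    def __post_init__(self) -> None:
        if self.occurrence < 1 or self.offset < 1:
            raise ValueError("occurrence and offset are 1-based")


def apply_mutation(record: ProteinRecord, mutation: AnchoredMutation,
                   region_intervals: Mapping[Region, tuple[int, int]] | None = None,
                   definitions: Mapping[str, MotifDefinition] | None = None,
                   ) -> ProteinRecord:
    """Apply an anchored point mutation; returns a new record.

    The anchor motif is rescanned in its constrained region; the requested
    occurrence and offset give the absolute position.  The mutant id is the
    parent id with the ``D610A``-style label appended after ``:``; the
    original record is left unmodified.
    """
    definitions = definitions or BUILTIN_MOTIFS
    if mutation.anchor_motif not in definitions:
        raise ValueError(f"unknown anchor motif {mutation.anchor_motif!r}")
    definition = definitions[mutation.anchor_motif]
    if mutation.offset > len(definition):
        raise ValueError(f"offset {mutation.offset} beyond motif length "
                         f"{len(definition)}")
    hits = scan_motifs(record, [definition], region_intervals)
    if len(hits) < mutation.occurrence:
        raise ValueError(
            f"{record.id}: motif {mutation.anchor_motif} has only {len(hits)} "
            f"hit(s), occurrence {mutation.occurrence} requested")
    hit = hits[mutation.occurrence - 1]
    position = hit.start + mutation.offset - 1
    found = record.residues[position - 1]
    expected = hit.matched[mutation.offset - 1]
    if found != expected:
        raise ValueError(
            f"{record.id}: anchored residue mismatch at {position}: "
            f"expected {expected!r}, found {found!r}")
    label = f"{found}{position}{mutation.replacement}"
    residues = (record.residues[:position - 1] + mutation.replacement
                + record.residues[position:])
    return ProteinRecord(f"{record.id}:{label}", residues,
                         description=f"{record.description} {label}".strip(),
                         species=record.species)


#: the Class I knockout recipe: first aspartate of DDxxD to alanine
CLASS_I_KNOCKOUT = AnchoredMutation("DDxxD", occurrence=1, offset=1,
                                    replacement="A")


def mutation_label(mutant: ProteinRecord) -> str:
    """The label appended by :func:`apply_mutation` (text after the last ':')."""
    return mutant.id.rsplit(":", 1)[-1]
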