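"""Domain-hit production and assembly of the TS / DTC screening datasets.

Two providers are supported.  External: ingested HMMER3 per-domain rows for
the Pfam α-domain profiles (PF03936, PF19086, PF06330) and the
squalene–hopene cyclase N-/C-terminal profiles (PF13249, PF13243) that
capture the γβ-didomain.  Internal: a desk-scale position-probability
profile scan built from the packaged synthetic templates, so the whole
pipeline runs without external searches.  The screen's substance is the
classification layered on top of the hits, not the hit-finding itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import AMINO_ACIDS, ProteinRecord, RawDomainRow
from . import synthetic_proteomes as _syn

logger = logging.getLogger(__name__)


class DomainClass(str, Enum):
    ALPHA_TS = "ALPHA_TS"
    GB_DTC = "GB_DTC"
    SHC_LIKE = "SHC_LIKE"


@dataclass(frozen=True)
class DomainHit:
    """A located domain region on a protein (1-based inclusive coordinates).

    ``score`` is the internal profile log-odds score in half-bits for
    internal hits, or −log10 of the per-domain e-value for external rows.
    """

    protein_id: str
    domain_class: DomainClass
    start: int
    end: int
    score: float
    provider: str = "internal"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.protein_id}: start > end")
        if not math.isfinite(self.score):
            raise ValueError(f"{self.protein_id}: non-finite score")


# Sub-hits of one domain split by the search are merged when separated by at
# most this many residues.
MERGE_GAP = 30


@dataclass(frozen=True)
class ScreenConfig:
    """Cutoffs and profile sets of the screening funnel.

    ``alpha_evalue_cutoff`` (1e-3) gates the α-domain HMM hits;
    ``gb_evalue_cutoff`` gates the γβ profile hits.  ``cdd_evalue_cutoff``
    (1e-2) and ``gb_blast_evalue_cutoff`` (1e-4, blastp against the
    reference DTC BAC47414.1) document the external confirmation steps and
    are metadata here: the relatedness filter is applied via
    ``align_phylo.closer_to_group`` or the internal SHC profile instead.
    ``internal_score_fraction`` sets per-class internal thresholds as a
    fraction of each profile's self-match score.
    """

    alpha_profile_ids: frozenset[str] = frozenset({"PF03936", "PF19086", "PF06330"})
    gb_cterm_profile_ids: frozenset[str] = frozenset({"PF13243"})
    gb_nterm_profile_ids: frozenset[str] = frozenset({"PF13249"})
    alpha_evalue_cutoff: float = 1e-3
    gb_evalue_cutoff: float = 1e-3
    cdd_evalue_cutoff: float = 1e-2
    gb_blast_evalue_cutoff: float = 1e-4
    reference_dtc_id: str = "BAC47414.1"
    internal_score_fraction: float = 0.6
    min_total_length: int = 0

    def __post_init__(self) -> None:
        for cutoff in (self.alpha_evalue_cutoff, self.gb_evalue_cutoff,
                       self.cdd_evalue_cutoff, self.gb_blast_evalue_cutoff):
            if cutoff <= 0:
                raise ValueError("e-value cutoffs must be positive")

    @property
    def gb_profile_ids(self) -> frozenset[str]:
        return self.gb_cterm_profile_ids | self.gb_nterm_profile_ids

    def profile_map(self) -> dict[str, str]:
        mapping = {p: "ALPHA" for p in self.alpha_profile_ids}
        mapping.update({p: "GB_CTERM" for p in self.gb_cterm_profile_ids})
        mapping.update({p: "GB_NTERM" for p in self.gb_nterm_profile_ids})
        return mapping

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScreenConfig":
        kwargs = dict(data)
        for key in ("alpha_profile_ids", "gb_cterm_profile_ids", "gb_nterm_profile_ids"):
            if key in kwargs:
                kwargs[key] = frozenset(kwargs[key])
        return cls(**kwargs)


def merge_intervals(intervals: Sequence[tuple[int, int, float]],
                    gap: int = MERGE_GAP) -> list[tuple[int, int, float]]:
    """Merge overlapping or near-adjacent (separation <= *gap*) scored
    intervals; the merged score is the maximum of the parts."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [ordered[0]]
    for start, end, score in ordered[1:]:
        last_start, last_end, last_score = merged[-1]
        if start <= last_end + gap + 1:
            merged[-1] = (last_start, max(last_end, end), max(last_score, score))
        else:
            merged.append((start, end, score))
    return merged


def hits_from_rows(rows: Iterable[RawDomainRow], config: ScreenConfig | None = None,
                   ) -> list[DomainHit]:
    """Turn ingested per-domain rows into merged :class:`DomainHit` objects.

    Rows must pass the per-class e-value cutoff.  A γβ-didomain (GB_DTC) hit
    is only emitted for proteins with evidence from both the N-terminal
    (PF13249-type) and C-terminal (PF13243-type) profiles; the hit spans
    their combined extent.
    """
    config = config or ScreenConfig()
    pmap = config.profile_map()
    alpha: dict[str, list[tuple[int, int, float]]] = {}
    gb: dict[str, dict[str, list[tuple[int, int, float]]]] = {}
    for row in rows:
        kind = pmap.get(row.query_profile_id)
        if kind is None:
            continue
        score = -math.log10(row.domain_ievalue)
        if kind == "ALPHA":
            if row.domain_ievalue <= config.alpha_evalue_cutoff:
                alpha.setdefault(row.target_id, []).append(
                    (row.env_start, row.env_end, score))
        else:
            if row.domain_ievalue <= config.gb_evalue_cutoff:
                gb.setdefault(row.target_id, {}).setdefault(kind, []).append(
                    (row.env_start, row.env_end, score))

    hits: list[DomainHit] = []
    for pid, intervals in alpha.items():
        for start, end, score in merge_intervals(intervals):
            hits.append(DomainHit(pid, DomainClass.ALPHA_TS, start, end, score,
                                  provider="external"))
    for pid, by_kind in gb.items():
        if "GB_NTERM" not in by_kind or "GB_CTERM" not in by_kind:
            continue
        combined = by_kind["GB_NTERM"] + by_kind["GB_CTERM"]
        merged = merge_intervals(combined)
        start = min(s for s, _, _ in merged)
        end = max(e for _, e, _ in merged)
        score = max(sc for _, _, sc in merged)
        hits.append(DomainHit(pid, DomainClass.GB_DTC, start, end, score,
                              provider="external"))
    hits.sort(key=lambda h: (h.protein_id, h.start, h.domain_class.value))
    return hits


class PositionProfile:
    """Position-probability profile over the 20 standard residues.

    Built from a single template with a flat 1/20 pseudocount; window scores
    are summed log2 odds against the uniform background.  X scores as the
    background (zero contribution).
    """

    def __init__(self, name: str, domain_class: DomainClass, template: str):
        self.name = name
        self.domain_class = domain_class
        self.length = len(template)
        index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        probs = np.full((self.length, 20), 1.0 / 20.0)
        for j, aa in enumerate(template):
            probs[j, index[aa]] += 1.0
        probs /= probs.sum(axis=1, keepdims=True)
        # column scores in bits vs uniform background; extra row for X = 0
        scores = np.log2(probs * 20.0)
        self.scores = np.vstack([scores.T, np.zeros((1, self.length))])  # (21, L)
        self.self_score = float(sum(scores[j, index[aa]]
                                    for j, aa in enumerate(template)))

    def window_scores(self, seq: str) -> np.ndarray:
        """Scores of all length-``L`` windows (stride 1)."""
        index = {aa: i for i, aa in enumerate(AMINO_ACIDS + "X")}
        encoded = np.fromiter((index[ch] for ch in seq), dtype=np.int64,
                              count=len(seq))
        n_windows = len(seq) - self.length + 1
        if n_windows <= 0:
            return np.empty(0)
        total = np.zeros(n_windows)
        for j in range(self.length):
            total += self.scores[encoded[j:j + n_windows], j]
        return total


def packaged_profiles() -> dict[DomainClass, PositionProfile]:
    """The three internal profiles built from the packaged templates."""
    return {
        DomainClass.ALPHA_TS: PositionProfile(
            "alpha_internal", DomainClass.ALPHA_TS, _syn.ALPHA_TEMPLATE),
        DomainClass.GB_DTC: PositionProfile(
            "gb_internal", DomainClass.GB_DTC, _syn.GB_TEMPLATE),
        DomainClass.SHC_LIKE: PositionProfile(
            "shc_internal", DomainClass.SHC_LIKE, _syn.SHC_TEMPLATE),
    }


def scan_internal(record: ProteinRecord,
                  profiles: Mapping[DomainClass, PositionProfile] | None = None,
                  config: ScreenConfig | None = None) -> list[DomainHit]:
    """Slide each internal profile over the sequence and emit merged hits.

    A window qualifies when its score reaches ``internal_score_fraction`` of
    the profile's self-match score (default 60%, calibrated so that random
    sequences produce no hits).  Sequences shorter than a profile yield no
    hits for it.  Deterministic.
    """
    profiles = profiles or packaged_profiles()
    config = config or ScreenConfig()
    hits: list[DomainHit] = []
    for domain_class, profile in profiles.items():
        threshold = config.internal_score_fraction * profile.self_score
        scores = profile.window_scores(record.residues)
        passing = np.flatnonzero(scores >= threshold)
        intervals = [(int(i) + 1, int(i) + profile.length, float(scores[i]))
                     for i in passing]
        for start, end, score in merge_intervals(intervals):
            hits.append(DomainHit(record.id, domain_class, start, end, score,
                                  provider="internal"))
    hits.sort(key=lambda h: (h.start, h.domain_class.value))
    return hits


def build_datasets(hits_by_protein: Mapping[str, Sequence[DomainHit]],
                   shc_flagged: frozenset[str] | set[str] = frozenset(),
                   ) -> tuple[set[str], set[str]]:
    """Assemble the α-domain TS set and the γβ-didomain DTC set.

    ``TS_set`` holds proteins with at least one ALPHA_TS hit; ``DTC_set``
    holds proteins with at least one GB_DTC hit that are not flagged as
    SHC-like (either by the internal SHC profile or by the relatedness
    filter).  The intersection of the two sets is the DCS candidate pool.
    """
    ts_set: set[str] = set()
    dtc_set: set[str] = set()
    for pid, hits in hits_by_protein.items():
        classes = {h.domain_class for h in hits}
        if DomainClass.ALPHA_TS in classes:
            ts_set.add(pid)
        if DomainClass.GB_DTC in classes and pid not in shc_flagged \
                and DomainClass.SHC_LIKE not in classes:
            dtc_set.add(pid)
    return ts_set, dtc_set
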