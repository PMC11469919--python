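"""End-to-end screening funnel: proteomes -> hits -> datasets -> intersection
-> motifs -> architecture calls -> splits -> trees -> reports.

Mirrors the genome-mining funnel for fused diterpene cyclase/synthases: the
α-domain TS dataset and the γβ-didomain DTC dataset are built independently
and their overlap (with the γβ-before-α order requirement) is the DCS
candidate pool.  Per-lineage species tabulation and prevalence summaries are
included.  All stages log one structured line (stage, in, out, dropped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import align_phylo, seqio
from .constructs import SplitConstruct, split_dcs
from .domain_detection import (DomainClass, DomainHit, ScreenConfig,
                               build_datasets, hits_from_rows,
                               packaged_profiles, scan_internal)
from .fusion_architecture import (ArchitectureCall, Call, architecture_table,
                                  call_architecture)
from .motif_engine import (BUILTIN_MOTIFS, MotifStatus, Region,
                           classify_motif_status, scan_motifs)
from .seqio import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LineageTable:
    """Per-lineage species counts: species with a DCS candidate, with any
    α-domain TS gene (fusions included), with any γβ DTC gene (fusions
    included), and total species."""

    frame: pd.DataFrame  # columns: lineage, n_DCS, n_TS_species, n_DTC_species, n_species


@dataclass
class ScreenReport:
    n_species: int
    n_proteins: int
    n_ts_genes: int
    n_dtc_genes: int
    n_ts_only: int
    n_dtc_only: int
    n_dcs_candidates: int
    n_atypical_order: int
    n_predicted_bifunctional: int
    prevalence_dcs: str
    calls: list[ArchitectureCall]
    candidate_table: pd.DataFrame
    splits: dict[str, tuple[SplitConstruct, SplitConstruct]]
    artifacts: dict[str, str] = field(default_factory=dict)
    lineage_table: LineageTable | None = None


def summarize_prevalence(n_hit_species: int, n_total_species: int) -> str:
    """Percentage of species carrying a feature, formatted like ``0.03%``.

    Rounded half-up to two decimals; for values of 1% or more, trailing
    zeros (and a bare decimal point) are trimmed, so 10.00 prints as
    ``10%`` while sub-percent values keep both decimals.
    """
    if n_total_species <= 0:
        raise ValueError("total species count must be positive")
    if not (0 <= n_hit_species <= n_total_species):
        raise ValueError("hit count must lie in [0, total]")
    pct = (Decimal(100) * Decimal(n_hit_species) / Decimal(n_total_species))
    pct = pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    text = f"{pct:.2f}"
    if pct >= 1:
        text = text.rstrip("0").rstrip(".")
    return text + "%"


def dtc_only_count(n_total_dtc_genes: int, n_tridomain: int) -> int:
    """γβ-didomain-only DTC genes: total γβ gene count minus the tridomain
    fusion candidates."""
    if n_tridomain > n_total_dtc_genes:
        raise ValueError("tridomain count exceeds total DTC gene count")
    return n_total_dtc_genes - n_tridomain


def _region_intervals(hits: Sequence[DomainHit]) -> dict[Region, tuple[int, int]]:
    regions: dict[Region, tuple[int, int]] = {}
    gb = [h for h in hits if h.domain_class in (DomainClass.GB_DTC,
                                                DomainClass.SHC_LIKE)]
    alpha = [h for h in hits if h.domain_class is DomainClass.ALPHA_TS]
    if gb:
        regions[Region.GB_REGION] = (min(h.start for h in gb),
                                     max(h.end for h in gb))
    if alpha:
        regions[Region.ALPHA_REGION] = (min(h.start for h in alpha),
                                        max(h.end for h in alpha))
    return regions


def _log_stage(stage: str, n_in: int, n_out: int, dropped: int = 0) -> None:
    logger.info("stage=%s in=%d out=%d dropped=%d", stage, n_in, n_out, dropped)


def classify_proteome(records: Sequence[ProteinRecord],
                      hits_by_protein: Mapping[str, Sequence[DomainHit]],
                      shc_flagged: frozenset[str] = frozenset(),
                      ) -> list[ArchitectureCall]:
    """Motif-classify and architecture-call every protein."""
    calls = []
    for rec in records:
        hits = list(hits_by_protein.get(rec.id, ()))
        regions = _region_intervals(hits)
        motif_hits = scan_motifs(rec, BUILTIN_MOTIFS.values(), regions or None)
        status = classify_motif_status(motif_hits)
        calls.append(call_architecture(rec, hits, status,
                                       shc_flagged=rec.id in shc_flagged))
    return calls


def run_screen(proteome_paths: Sequence[str | Path],
               config: ScreenConfig | None = None,
               hits_path: str | Path | None = None,
               lineage_map: Mapping[str, str] | None = None,
               out_dir: str | Path | None = None,
               seed: int = 0,
               build_trees: bool = True,
               internal_scan: bool | None = None) -> ScreenReport:
    """Run the full screening funnel over one or more proteome FASTA files.

    Domain evidence comes either from an ingested HMMER3 per-domain table
    (``hits_path``) or from the internal profile scanner — exactly one of
    the two.  Deterministic given inputs, config and seed.
    """
    config = config or ScreenConfig()
    if hits_path is not None and internal_scan:
        raise ValueError("supply either a hits file or internal scanning, not both")
    if not proteome_paths:
        raise ValueError("at least one proteome file is required")

    records: list[ProteinRecord] = []
    seen: dict[str, str] = {}
    for path in proteome_paths:
        for rec in seqio.read_fasta(path):
            if rec.id in seen:
                if seen[rec.id] != rec.residues:
                    raise ValueError(f"conflicting sequences for duplicate id {rec.id!r}")
                continue  # identical duplicate entries are de-duplicated
            seen[rec.id] = rec.residues
            records.append(rec)
    if not records:
        raise ValueError("no proteins parsed from input")
    species = {r.species for r in records if r.species}
    _log_stage("read_proteomes", len(proteome_paths), len(records))

    hits_by_protein: dict[str, list[DomainHit]] = {}
    if hits_path is not None:
        rows = seqio.read_domtblout(hits_path, config.profile_map())
        known = set(seen)
        for row in rows:
            if row.target_id not in known:
                raise ValueError(
                    f"hits file references protein {row.target_id!r} absent "
                    "from the proteome input")
        for hit in hits_from_rows(rows, config):
            hits_by_protein.setdefault(hit.protein_id, []).append(hit)
    else:
        profiles = packaged_profiles()
        for rec in records:
            found = scan_internal(rec, profiles, config)
            if found:
                hits_by_protein[rec.id] = found
    n_hits = sum(len(v) for v in hits_by_protein.values())
    _log_stage("domain_detection", len(records), n_hits)

    ts_set, dtc_set = build_datasets(hits_by_protein)
    _log_stage("build_datasets", n_hits, len(ts_set) + len(dtc_set))

    calls = classify_proteome(records, hits_by_protein)
    by_call: dict[Call, list[ArchitectureCall]] = {}
    for call in calls:
        by_call.setdefault(call.call, []).append(call)
    candidates = by_call.get(Call.DCS_CANDIDATE, [])
    rec_by_id = {r.id: r for r in records}
    if config.min_total_length > 0:
        before = len(candidates)
        candidates = [c for c in candidates
                      if len(rec_by_id[c.protein_id]) >= config.min_total_length]
        _log_stage("min_length_gate", before, len(candidates),
                   before - len(candidates))
    _log_stage("call_architecture", len(calls), len(candidates))

    splits: dict[str, tuple[SplitConstruct, SplitConstruct]] = {}
    for call in candidates:
        splits[call.protein_id] = split_dcs(rec_by_id[call.protein_id], call)
    _log_stage("split_candidates", len(candidates), len(splits))

    report = ScreenReport(
        n_species=len(species),
        n_proteins=len(records),
        n_ts_genes=len(ts_set),
        n_dtc_genes=len(dtc_set),
        n_ts_only=len(by_call.get(Call.TS_ONLY, [])),
        n_dtc_only=len(by_call.get(Call.DTC_ONLY, [])),
        n_dcs_candidates=len(candidates),
        n_atypical_order=len(by_call.get(Call.DCS_ATYPICAL_ORDER, [])),
        n_predicted_bifunctional=sum(c.predicted_bifunctional for c in candidates),
        prevalence_dcs=summarize_prevalence(
            len({rec_by_id[c.protein_id].species for c in candidates
                 if rec_by_id[c.protein_id].species}),
            max(len(species), 1)),
        calls=calls,
        candidate_table=architecture_table(candidates),
        splits=splits,
    )
    if lineage_map is not None:
        report.lineage_table = tabulate_lineages(calls, lineage_map,
                                                 {r.id: r.species for r in records})

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = architecture_table(calls)
        seqio.write_tsv(table, out / "architecture_calls.tsv")
        report.artifacts["architecture_calls"] = str(out / "architecture_calls.tsv")
        seqio.write_tsv(report.candidate_table, out / "dcs_candidates.tsv")
        report.artifacts["dcs_candidates"] = str(out / "dcs_candidates.tsv")
        if report.lineage_table is not None:
            seqio.write_tsv(report.lineage_table.frame, out / "lineage_table.tsv")
            report.artifacts["lineage_table"] = str(out / "lineage_table.tsv")
        if splits:
            split_records = []
            for nterm, cterm in splits.values():
                split_records.extend([nterm.as_record(), cterm.as_record()])
            seqio.write_fasta(split_records, out / "split_constructs.fasta")
            report.artifacts["split_constructs"] = str(out / "split_constructs.fasta")

    if build_trees:
        _build_part_trees(report, rec_by_id, by_call, seed,
                          Path(out_dir) if out_dir is not None else None)
    return report


def _build_part_trees(report: ScreenReport, rec_by_id, by_call, seed, out_dir):
    """NJ trees of (a) all α parts — candidate α splits plus α-only TSs —
    and (b) all γβ parts — candidate γβ splits plus γβ-only DTCs."""
    alpha_parts = [c.as_record() for _, c in report.splits.values()]
    alpha_parts += [rec_by_id[c.protein_id]
                    for c in by_call.get(Call.TS_ONLY, [])]
    gb_parts = [n.as_record() for n, _ in report.splits.values()]
    gb_parts += [rec_by_id[c.protein_id]
                 for c in by_call.get(Call.DTC_ONLY, [])]
    for name, parts in (("alpha_tree", alpha_parts), ("gb_tree", gb_parts)):
        if len(parts) < 3:
            continue
        alignment = align_phylo.progressive_msa(parts)
        tree = align_phylo.neighbor_joining(
            align_phylo.poisson_distance(alignment))
        report.artifacts[name] = seqio.newick_string(tree)
        if out_dir is not None:
            seqio.write_newick(tree, out_dir / f"{name}.nwk")
    _log_stage("build_trees", len(alpha_parts) + len(gb_parts),
               sum(1 for k in ("alpha_tree", "gb_tree") if k in report.artifacts))


def tabulate_lineages(calls: Sequence[ArchitectureCall],
                      lineage_map: Mapping[str, str],
                      species_of_protein: Mapping[str, str]) -> LineageTable:
    """Per-lineage counts of species with DCS candidates, TS genes
    (α-domain-containing, fusions included), DTC genes (γβ-containing,
    fusions included) and total species.  Species missing from the lineage
    map fall into ``unassigned``."""
    def lineage_of(sp: str) -> str:
        return lineage_map.get(sp, "unassigned")

    dcs_species: dict[str, set[str]] = {}
    ts_species: dict[str, set[str]] = {}
    dtc_species: dict[str, set[str]] = {}
    for call in calls:
        sp = species_of_protein.get(call.protein_id, "")
        if not sp:
            continue
        lin = lineage_of(sp)
        classes = {h.domain_class for h in call.hits}
        if call.call is Call.DCS_CANDIDATE:
            dcs_species.setdefault(lin, set()).add(sp)
        if DomainClass.ALPHA_TS in classes:
            ts_species.setdefault(lin, set()).add(sp)
        if DomainClass.GB_DTC in classes and call.call is not Call.SHC_LIKE:
            dtc_species.setdefault(lin, set()).add(sp)

    totals: dict[str, set[str]] = {}
    for sp in set(lineage_map) | {s for s in species_of_protein.values() if s}:
        totals.setdefault(lineage_of(sp), set()).add(sp)

    rows = []
    for lin in sorted(totals):
        rows.append({
            "lineage": lin,
            "n_DCS": len(dcs_species.get(lin, ())),
            "n_TS_species": len(ts_species.get(lin, ())),
            "n_DTC_species": len(dtc_species.get(lin, ())),
            "n_species": len(totals[lin]),
        })
    frame = pd.DataFrame(rows, columns=["lineage", "n_DCS", "n_TS_species",
                                        "n_DTC_species", "n_species"])
    return LineageTable(frame=frame)
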