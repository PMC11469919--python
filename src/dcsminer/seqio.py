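"""Readers and writers for the external formats used across the pipeline.

FASTA (protein), HMMER3 per-domain tables (``--domtblout``), Newick trees,
tab-separated reports and the YAML configuration file.  All sequence
coordinates in this package are 1-based and inclusive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO as _BioSeqIO
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: the 20 standard amino acids plus X (unknown residue)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class ProteinRecord:
    """A single identified amino-acid sequence with an optional species tag."""

    id: str
    residues: str
    description: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"protein id must be a non-empty token, got {self.id!r}")
        if len(self.residues) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in VALID_RESIDUES:
                raise ValueError(
                    f"{self.id}: illegal residue character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RawDomainRow:
    """One data line of a HMMER3 per-domain table (envelope coordinates)."""

    target_id: str
    query_profile_id: str
    full_seq_evalue: float
    domain_ievalue: float
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if self.full_seq_evalue <= 0 or self.domain_ievalue <= 0:
            raise ValueError(f"{self.target_id}: e-values must be positive")
        if not (1 <= self.env_start <= self.env_end):
            raise ValueError(
                f"{self.target_id}: bad envelope coordinates "
                f"{self.env_start}..{self.env_end}"
            )


_SPECIES_TOKEN = "species="


def read_fasta(path: str | Path, species_token: str = _SPECIES_TOKEN) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Wrapped sequence lines are concatenated, lowercase residues are folded to
    uppercase and a single trailing ``*`` stop symbol is stripped.  The species
    tag is parsed from the header text following *species_token* when present.
    Duplicate ids and illegal residue characters raise ``ValueError``; an empty
    file yields an empty list.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        description = rec.description[len(rec.id):].strip()
        species = ""
        for token in description.split():
            if token.startswith(species_token):
                species = token[len(species_token):]
                break
        records.append(
            ProteinRecord(id=rec.id, residues=residues, description=description,
                          species=species)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records to FASTA, preserving the species tag in the header."""
    with open(path, "w") as fh:
        for rec in records:
            desc = rec.description
            if rec.species and f"{_SPECIES_TOKEN}{rec.species}" not in desc:
                desc = f"{_SPECIES_TOKEN}{rec.species} {desc}".strip()
            header = f">{rec.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i:i + wrap] + "\n")


# HMMER3 domtblout layout: 22 whitespace-delimited columns followed by a free
# text description.  Column indices used below follow the documented order.
_DOMTBL_MIN_COLS = 22
_COL_TARGET = 0
_COL_QUERY_NAME = 3
_COL_QUERY_ACC = 4
_COL_FULL_EVALUE = 6
_COL_DOM_IEVALUE = 12
_COL_ENV_FROM = 19
_COL_ENV_TO = 20


def strip_profile_version(accession: str) -> str:
    """Drop a Pfam-style version suffix: ``PF13243.8`` -> ``PF13243``."""
    return accession.split(".", 1)[0]


def read_domtblout(path: str | Path, profile_map: Mapping[str, str]) -> list[RawDomainRow]:
    """Parse a HMMER3 ``--domtblout`` table into :class:`RawDomainRow` rows.

    *profile_map* maps profile accessions (version suffixes ignored) to domain
    classes; rows whose profile is absent from the map are dropped and the
    dropped count is logged.  Envelope coordinates are used throughout.
    """
    mapped = {strip_profile_version(k) for k in profile_map}
    rows: list[RawDomainRow] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _DOMTBL_MIN_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected at least {_DOMTBL_MIN_COLS} "
                    f"columns in domtblout line, found {len(cols)}"
                )
            acc = cols[_COL_QUERY_ACC]
            if acc == "-" or not acc.startswith("PF"):
                acc = cols[_COL_QUERY_NAME]
            acc = strip_profile_version(acc)
            if acc not in mapped:
                dropped += 1
                continue
            rows.append(
                RawDomainRow(
                    target_id=cols[_COL_TARGET],
                    query_profile_id=acc,
                    full_seq_evalue=float(cols[_COL_FULL_EVALUE]),
                    domain_ievalue=float(cols[_COL_DOM_IEVALUE]),
                    env_start=int(cols[_COL_ENV_FROM]),
                    env_end=int(cols[_COL_ENV_TO]),
                )
            )
    if dropped:
        logger.info("read_domtblout: dropped %d rows with unmapped profiles", dropped)
    return rows


def _format_branch_length(value: float | None) -> str:
    if value is None:
        return ""
    return ":" + format(float(value), ".6g")


_NEWICK_SPECIAL = set("()[]':;, \t")


def _newick_label(name: str) -> str:
    if any(ch in _NEWICK_SPECIAL for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode) -> str:
    if node.is_tip():
        if not node.name:
            raise ValueError("unnamed leaf in tree")
        return _newick_label(node.name) + _format_branch_length(node.length)
    inner = ",".join(_newick_node(child) for child in node.children)
    label = _newick_label(node.name) if node.name else ""
    return f"({inner}){label}" + _format_branch_length(node.length)


def newick_string(tree: TreeNode) -> str:
    """Serialize a tree to a whitespace-free Newick string.

    Branch lengths are written with 6 significant digits; internal node names
    (integer bootstrap supports) are emitted as labels after the closing
    parenthesis.  Unnamed leaves raise ``ValueError``.
    """
    return _newick_node(tree) + ";"


def write_newick(tree: TreeNode, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def read_newick(source: str | Path) -> TreeNode:
    """Parse Newick from a path or a literal string into a ``TreeNode``."""
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        if "(" not in text:  # no tree structure: treat as a path
            text = Path(text).read_text()
    return TreeNode.read(StringIO(text), convert_underscores=False)


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as UTF-8 TSV with a header row and no index."""
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_config(path: str | Path) -> dict:
    """Load the YAML configuration file (``screen:`` and ``motifs:`` keys)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level of config must be a mapping")
    return data


def read_lineage_map(path: str | Path) -> dict[str, str]:
    """Read a two-column species -> lineage TSV (header row required)."""
    frame = read_tsv(path)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: lineage map needs two columns (species, lineage)")
    species_col, lineage_col = frame.columns[:2]
    return dict(zip(frame[species_col], frame[lineage_col]))
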