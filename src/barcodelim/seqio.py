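"""Alignment and tree I/O plus alignment site statistics.

Alignments are pre-aligned, fixed-length nucleotide matrices (the pipeline
never aligns sequences itself). Each sequence carries a role — ``specimen``
(a field sample to be identified), ``reference`` (a named sequence from a
curated library), or ``outgroup`` (used only for rooting). IUPAC ambiguity
codes and ``N`` are kept in storage but treated as missing data by the site
statistics and by the distance module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ROLES = ("specimen", "reference", "outgroup")

#: Permitted characters: unambiguous bases, IUPAC ambiguity codes, N, gap.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

# uint8 encoding used throughout: A=0, C=1, G=2, T=3, anything else = 4.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class AlignmentError(ValueError):
    """Malformed alignment input (shape, duplicate id, illegal character)."""


@dataclass
class Alignment:
    """A fixed-length multiple sequence alignment for one locus.

    Parameters
    ----------
    ids
        Unique sequence identifiers, order preserved from input.
    sequences
        Upper-case aligned sequences, all of identical length.
    locus_name
        Label for the locus (e.g. ``"tufA"`` or ``"ITS"``).
    roles
        Map id -> one of :data:`ROLES`. Ids absent from the map default to
        ``"specimen"``.
    """

    ids: list[str]
    sequences: list[str]
    locus_name: str = "locus"
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment has no sequences")
        if len(self.ids) != len(self.sequences):
            raise AlignmentError("ids and sequences differ in number")
        seen: set[str] = set()
        for sid in self.ids:
            if sid in seen:
                raise AlignmentError(f"duplicate sequence id {sid!r}")
            seen.add(sid)
        self.sequences = [s.upper() for s in self.sequences]
        length = len(self.sequences[0])
        if length < 1:
            raise AlignmentError("alignment length must be >= 1")
        for sid, seq in zip(self.ids, self.sequences):
            if len(seq) != length:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(seq)}, expected {length}"
                )
            for pos, ch in enumerate(seq):
                if ch not in IUPAC_CHARS:
                    raise AlignmentError(
                        f"illegal character {ch!r} in sequence {sid!r} "
                        f"at column {pos + 1}"  # 1-based in messages
                    )
        roles = {}
        for sid in self.ids:
            role = self.roles.get(sid, "specimen")
            if role not in ROLES:
                raise AlignmentError(f"unknown role {role!r} for id {sid!r}")
            roles[sid] = role
        self.roles = roles

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def sequence(self, sid: str) -> str:
        return self.sequences[self.ids.index(sid)]

    def ids_with_role(self, role: str) -> list[str]:
        return [i for i in self.ids if self.roles[i] == role]

    def to_codes(self) -> np.ndarray:
        """Return the (n, length) uint8 code matrix (A=0,C=1,G=2,T=3, other=4)."""
        raw = np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(self.n, self.length)
        return _CODE[raw]

    def subset(self, keep_ids: Iterable[str]) -> "Alignment":
        keep = list(keep_ids)
        idx = {sid: k for k, sid in enumerate(self.ids)}
        missing = [s for s in keep if s not in idx]
        if missing:
            raise AlignmentError(f"ids not in alignment: {missing}")
        return Alignment(
            ids=keep,
            sequences=[self.sequences[idx[s]] for s in keep],
            locus_name=self.locus_name,
            roles={s: self.roles[s] for s in keep},
        )

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        """Column subset (0-based indices), preserving ids and roles."""
        cols = np.asarray(columns, dtype=int)
        return Alignment(
            ids=list(self.ids),
            sequences=["".join(s[c] for c in cols) for s in self.sequences],
            locus_name=self.locus_name,
            roles=dict(self.roles),
        )


@dataclass(frozen=True)
class SiteStats:
    """Per-alignment site counts over unambiguous bases only."""

    alignment_length: int
    n_variable: int
    n_parsimony_informative: int
    n_singleton: int


def read_fasta(
    path: str | Path,
    locus_name: str = "locus",
    role_map: Mapping[str, str] | None = None,
    default_role: str = "specimen",
) -> Alignment:
    """Read an aligned multi-FASTA file into an :class:`Alignment`.

    Record order is preserved and sequences are upper-cased. Roles come from
    ``role_map`` (id -> role), falling back to ``default_role``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    roles = {i: (role_map or {}).get(i, default_role) for i in ids}
    return Alignment(ids=ids, sequences=seqs, locus_name=locus_name, roles=roles)


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(alignment.ids, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def site_statistics(alignment: Alignment) -> SiteStats:
    """Count variable, parsimony-informative, and singleton columns.

    Only unambiguous bases {A,C,G,T} are considered; gaps, N and ambiguity
    codes are missing data. A column is variable if >= 2 distinct bases occur,
    parsimony-informative if >= 2 distinct bases each occur in >= 2 sequences,
    and a singleton site if variable but not informative. An all-gap column is
    non-variable.
    """
    codes = alignment.to_codes()
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])  # (4, L)
    n_distinct = (counts > 0).sum(axis=0)
    n_shared = (counts >= 2).sum(axis=0)
    variable = n_distinct >= 2
    informative = n_shared >= 2
    n_var = int(variable.sum())
    n_pi = int((variable & informative).sum())
    return SiteStats(
        alignment_length=alignment.length,
        n_variable=n_var,
        n_parsimony_informative=n_pi,
        n_singleton=n_var - n_pi,
    )


# -- metadata and reference tables (TSV with headers) ----------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a specimen metadata TSV: specimen_id, site_code, morphotype."""
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"specimen_id", "site_code"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    if "morphotype" not in meta.columns:
        meta["morphotype"] = ""
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_reference_table(path: str | Path) -> pd.DataFrame:
    """Read a reference TSV: sequence_id, species, locus, accession."""
    refs = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sequence_id", "species"}
    missing = required - set(refs.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    for col in ("locus", "accession"):
        if col not in refs.columns:
            refs[col] = ""
    if (refs["species"] == "").any():
        raise ValueError("reference table has empty species names")
    if refs.duplicated(subset=["sequence_id", "locus"]).any():
        dups = refs.loc[
            refs.duplicated(subset=["sequence_id", "locus"]), "sequence_id"
        ].tolist()
        raise ValueError(f"duplicate reference sequence ids within a locus: {dups}")
    return refs


def write_reference_table(refs: pd.DataFrame, path: str | Path) -> None:
    refs.to_csv(path, sep="\t", index=False)


# -- Newick ----------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; internal node labels (supports) are preserved."""
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return tree


def parse_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]
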