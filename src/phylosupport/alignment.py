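"""Protein alignment container and FASTA / relaxed-PHYLIP I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO

from .alphabet import MISSING, N_STATES, decode, encode


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Taxa x sites amino-acid matrix with gap/missing states.

    ``residues`` holds int8 codes: 0-19 for amino acids in ARNDCQEGHILKMFPSTWYV
    order, 20 for gap or unknown ('X').
    """

    taxon_names: list[str]
    residues: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=np.int8)
        if self.residues.ndim != 2:
            raise AlignmentError("residue matrix must be 2-D (taxa x sites)")
        if self.residues.shape[0] != len(self.taxon_names):
            raise AlignmentError("one row per taxon required")
        if self.residues.shape[1] < 1:
            raise AlignmentError("alignment must have at least one site")
        if len(set(self.taxon_names)) != len(self.taxon_names):
            raise AlignmentError("taxon names must be unique")
        if self.residues.min() < 0 or self.residues.max() > MISSING:
            raise AlignmentError("residue codes outside the 22-symbol alphabet")

    @property
    def n_taxa(self) -> int:
        return self.residues.shape[0]

    @property
    def n_sites(self) -> int:
        return self.residues.shape[1]

    @classmethod
    def from_sequences(cls, taxon_names, sequences, name: str = "") -> "Alignment":
        """Build from residue strings (case-insensitive; '-'/'X' = missing)."""
        rows = [encode(s) for s in sequences]
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        return cls(list(taxon_names), np.vstack(rows), name=name)

    def sequence(self, taxon: str) -> str:
        return decode(self.residues[self.taxon_names.index(taxon)])

    def subset_taxa(self, keep) -> "Alignment":
        """Restrict to the given taxa (original row order preserved)."""
        keep = set(keep)
        idx = [i for i, t in enumerate(self.taxon_names) if t in keep]
        if not idx:
            raise AlignmentError("no requested taxa present in alignment")
        return Alignment([self.taxon_names[i] for i in idx],
                         self.residues[idx], name=self.name)

    def subset_sites(self, site_indices) -> "Alignment":
        idx = np.asarray(site_indices, dtype=int)
        return Alignment(list(self.taxon_names), self.residues[:, idx], name=self.name)

    def residue_counts(self) -> np.ndarray:
        """Counts of the 20 amino acids over the whole matrix (missing ignored)."""
        flat = self.residues[self.residues < N_STATES]
        return np.bincount(flat, minlength=N_STATES).astype(float)

    def taxon_set(self) -> set[str]:
        return set(self.taxon_names)


def concatenate(alignments, name: str = "concat") -> Alignment:
    """Concatenate genes site-wise over the union of taxa (missing -> gaps)."""
    alignments = list(alignments)
    if not alignments:
        raise AlignmentError("nothing to concatenate")
    taxa = sorted({t for a in alignments for t in a.taxon_names})
    total = sum(a.n_sites for a in alignments)
    mat = np.full((len(taxa), total), MISSING, dtype=np.int8)
    pos = 0
    index = {t: i for i, t in enumerate(taxa)}
    for a in alignments:
        rows = [index[t] for t in a.taxon_names]
        mat[rows, pos:pos + a.n_sites] = a.residues
        pos += a.n_sites
    return Alignment(taxa, mat, name=name)


# ---------------------------------------------------------------------------
# I/O

def read_alignment(path, fmt: str | None = None, name: str | None = None) -> Alignment:
    """Read FASTA or (relaxed sequential/interleaved) PHYLIP.

    ``fmt`` in {"fasta", "phylip"}; inferred from the file when omitted
    (PHYLIP files open with the "ntaxa nsites" header line).
    """
    path = str(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline().strip()
        fmt = "fasta" if first.startswith(">") else "phylip"
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise AlignmentError(f"no sequences in {path}")
        return Alignment.from_sequences(
            [r.id for r in records], [str(r.seq) for r in records],
            name=name or "")
    if fmt == "phylip":
        aln = AlignIO.read(path, "phylip-relaxed")
        return Alignment.from_sequences(
            [r.id for r in aln], [str(r.seq) for r in aln], name=name or "")
    raise AlignmentError(f"unknown alignment format: {fmt}")


def write_alignment(aln: Alignment, path, fmt: str = "fasta") -> None:
    path = str(path)
    if fmt == "fasta":
        with open(path, "w") as fh:
            for i, t in enumerate(aln.taxon_names):
                fh.write(f">{t}\n{decode(aln.residues[i])}\n")
    elif fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f" {aln.n_taxa} {aln.n_sites}\n")
            width = max(len(t) for t in aln.taxon_names) + 2
            for i, t in enumerate(aln.taxon_names):
                fh.write(f"{t:<{width}}{decode(aln.residues[i])}\n")
    else:
        raise AlignmentError(f"unknown alignment format: {fmt}")
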