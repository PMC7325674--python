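"""Gene alignments: reading, filtering, selection, and supermatrix concatenation.

The pipeline starts from per-gene multiple sequence alignments of single-copy
orthologs (aligned FASTA, DNA).  Genes are filtered column-wise — either to
gap-free conserved blocks (a strict, Gblocks-like criterion) or by a per-column
gap-fraction ceiling (a relaxed, GUIDANCE-like criterion) — selected by length
and taxon coverage, and concatenated into a supermatrix with a partition record
per gene.

Alignments are stored column-major friendly as uint8 code matrices; the
alphabet is {A, C, G, T, -, N, ?} with IUPAC ambiguity codes folded into N.
Gap (-), N and ? all count as missing for filtering and likelihood purposes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGT-N?"
CODE_OF = {c: i for i, c in enumerate(ALPHABET)}
GAP_CODES = (4, 5, 6)  # '-', 'N', '?'
_AMBIGUOUS = "RYSWKMBDHVU"

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _i in CODE_OF.items():
    _ENCODE_LUT[ord(_c)] = _i
    _ENCODE_LUT[ord(_c.lower())] = _i
for _c in _AMBIGUOUS:
    _ENCODE_LUT[ord(_c)] = CODE_OF["N"]
    _ENCODE_LUT[ord(_c.lower())] = CODE_OF["N"]
_ENCODE_LUT[ord(".")] = CODE_OF["-"]


def encode_sequence(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if (codes == 255).any():
        bad = chr(raw[int(np.argmax(codes == 255))])
        raise ValueError(f"illegal character {bad!r} in sequence")
    return codes


def decode_row(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


@dataclass
class GeneAlignment:
    """One ortholog's aligned DNA matrix over a subset of the taxon universe."""

    gene_id: str
    taxa: list[str]
    codes: np.ndarray  # (n_taxa, length) uint8

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError(f"{self.gene_id}: code matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"{self.gene_id}: duplicate taxon labels")

    @classmethod
    def from_seqs(cls, gene_id: str, seqs: Mapping[str, str]) -> "GeneAlignment":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise ValueError(f"{gene_id}: ragged alignment (lengths {sorted(lengths)})")
        length = lengths.pop() if lengths else 0
        codes = np.empty((len(taxa), length), dtype=np.uint8)
        for i, t in enumerate(taxa):
            codes[i] = encode_sequence(seqs[t].upper())
        return cls(gene_id, taxa, codes)

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def seqs(self) -> dict[str, str]:
        return {t: decode_row(self.codes[i]) for i, t in enumerate(self.taxa)}

    def sequence(self, taxon: str) -> str:
        return decode_row(self.codes[self.taxa.index(taxon)])

    def take_columns(self, idx: Sequence[int] | np.ndarray, gene_id: str | None = None) -> "GeneAlignment":
        return GeneAlignment(gene_id or self.gene_id, list(self.taxa), self.codes[:, idx])

    def subset_taxa(self, taxa: Sequence[str]) -> "GeneAlignment":
        rows = [self.taxa.index(t) for t in taxa]
        return GeneAlignment(self.gene_id, list(taxa), self.codes[rows])

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_taxa, length) mask of gap/N/? cells."""
        return self.codes >= 4


@dataclass
class Partition:
    gene_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SupermatrixBundle:
    """Concatenated supermatrix plus the gene → column-range partition table."""

    matrix: GeneAlignment
    partitions: list[Partition]
    missing_char: str = "?"

    def __post_init__(self):
        expected = 0
        for p in self.partitions:
            if p.start != expected or p.end < p.start:
                raise ValueError("partitions must be sorted, contiguous and disjoint")
            expected = p.end
        if expected != self.matrix.length:
            raise ValueError("partitions do not cover the matrix")

    @property
    def length(self) -> int:
        return self.matrix.length

    @property
    def taxa(self) -> list[str]:
        return self.matrix.taxa

    def gene_slice(self, gene_id: str) -> GeneAlignment:
        for p in self.partitions:
            if p.gene_id == gene_id:
                return self.matrix.take_columns(np.arange(p.start, p.end), gene_id=gene_id)
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def read_gene_alignment(path: str | Path) -> GeneAlignment:
    path = Path(path)
    seqs: dict[str, str] = {}
    length: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path.name}: duplicate taxon {rec.id!r}")
        s = str(rec.seq).upper()
        if length is None:
            length = len(s)
        elif len(s) != length:
            raise ValueError(
                f"{path.name}: ragged alignment — record {rec.id!r} has length "
                f"{len(s)}, expected {length}"
            )
        seqs[rec.id] = s
    if not seqs:
        raise ValueError(f"{path.name}: no records")
    return GeneAlignment.from_seqs(path.stem, seqs)


def read_gene_alignments(paths: Iterable[str | Path]) -> list[GeneAlignment]:
    """Read one aligned FASTA per gene; record ids are taxon labels."""
    return [read_gene_alignment(p) for p in paths]


# ---------------------------------------------------------------------------
# column filters
# ---------------------------------------------------------------------------


def filter_gap_free_blocks(
    aln: GeneAlignment, min_block_len: int = 10, min_conserved_frac: float = 0.5
) -> GeneAlignment:
    """Strict trimming to gap-free conserved blocks.

    Keeps only columns with zero gap/N/? characters, grouped into maximal
    runs of consecutive clean columns.  Runs shorter than `min_block_len`
    are discarded, as are runs in which fewer than `min_conserved_frac` of
    columns are conserved (a majority residue shared by more than half the
    taxa).  The output may be empty; downstream gene selection treats empty
    genes like any other short gene.
    """
    if min_block_len < 1:
        raise ValueError("min_block_len must be >= 1")
    if not 0.0 <= min_conserved_frac <= 1.0:
        raise ValueError("min_conserved_frac must be in [0, 1]")
    clean = ~aln.missing_mask().any(axis=0)
    keep: list[np.ndarray] = []
    n = aln.n_taxa
    for run in _runs(clean):
        if len(run) < min_block_len:
            continue
        if min_conserved_frac > 0:
            counts = np.stack([(aln.codes[:, run] == b).sum(axis=0) for b in range(4)])
            conserved = counts.max(axis=0) > n / 2.0
            if conserved.mean() < min_conserved_frac:
                continue
        keep.append(run)
    idx = np.concatenate(keep) if keep else np.empty(0, dtype=int)
    return aln.take_columns(idx)


def _runs(mask: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of consecutive True indices."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    return np.split(idx, breaks)


def filter_columns_by_gap_fraction(aln: GeneAlignment, max_gap_frac: float = 0.5) -> GeneAlignment:
    """Keep columns whose gap/N/? fraction is strictly below `max_gap_frac`."""
    if not 0.0 <= max_gap_frac <= 1.0:
        raise ValueError("max_gap_frac must be in [0, 1]")
    if aln.n_taxa == 0 or aln.length == 0:
        return aln.take_columns(np.empty(0, dtype=int))
    frac = aln.missing_mask().mean(axis=0)
    return aln.take_columns(np.flatnonzero(frac < max_gap_frac))


def select_genes(
    genes: Sequence[GeneAlignment],
    min_len: int = 1000,
    require_taxa: Iterable[str] = (),
) -> list[GeneAlignment]:
    """Genes strictly longer than `min_len` bp that contain all `require_taxa`."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    req = set(require_taxa)
    return [g for g in genes if g.length > min_len and req <= set(g.taxa)]


# ---------------------------------------------------------------------------
# zero-missing subset
# ---------------------------------------------------------------------------


def build_no_missing_dataset(
    genes: Sequence[GeneAlignment],
    all_taxa: Iterable[str],
    protected_taxa: Iterable[str] = (),
    target_genes: int | None = None,
) -> tuple[list[GeneAlignment], list[str]]:
    """Greedy taxon dropping toward a complete (no missing gene) data block.

    Iteratively removes the non-protected taxon present in the fewest genes
    (ties broken by label).  With no target, a removal is accepted only while
    it increases the number of genes covering every retained taxon (pure
    hill climbing).  Because a single removal often cannot create a complete
    gene when several incomplete taxa remain, `target_genes` allows the
    greedy walk to push through such plateaus: removals continue — gain or
    not — until at least that many complete genes are available (or no
    non-protected taxa remain).  Protected taxa are never removed.  Returns
    the covering genes with rows restricted to the retained taxa, and the
    retained taxon list.
    """
    taxa = sorted(set(all_taxa))
    protected = set(protected_taxa)
    if not protected <= set(taxa):
        raise ValueError("protected_taxa must be a subset of all_taxa")
    membership = {t: {g.gene_id for g in genes if t in g.taxa} for t in taxa}
    for t in protected:
        if not membership[t]:
            raise ValueError(f"protected taxon {t!r} is absent from every gene")

    def complete_count(kept: list[str]) -> int:
        kept_set = set(kept)
        return sum(1 for g in genes if kept_set <= set(g.taxa))

    kept = list(taxa)
    current = complete_count(kept)
    while True:
        if target_genes is not None and current >= target_genes:
            break
        candidates = [t for t in kept if t not in protected]
        if not candidates or len(kept) <= 1:
            break
        victim = min(candidates, key=lambda t: (len(membership[t]), t))
        trial = [t for t in kept if t != victim]
        gain = complete_count(trial)
        if gain > current or target_genes is not None:
            kept, current = trial, gain
        else:
            break

    kept_set = set(kept)
    covering = [g.subset_taxa(kept) for g in genes if kept_set <= set(g.taxa)]
    return covering, kept


# ---------------------------------------------------------------------------
# concatenation and supermatrix I/O
# ---------------------------------------------------------------------------


def concatenate_supermatrix(
    genes: Sequence[GeneAlignment],
    taxa: Sequence[str],
    missing_char: str = "?",
) -> SupermatrixBundle:
    """Concatenate genes over an explicit taxon universe, padding absences.

    A taxon absent from a gene is padded with `missing_char` over that gene's
    partition.  Partition ranges are 0-based half-open, in input gene order.
    """
    if not genes:
        raise ValueError("no genes to concatenate")
    if not taxa:
        raise ValueError("empty taxon list")
    taxa = list(taxa)
    taxon_index = {t: i for i, t in enumerate(taxa)}
    if missing_char not in CODE_OF:
        raise ValueError(f"missing_char must be one of {ALPHABET!r}")
    pad = CODE_OF[missing_char]

    total = sum(g.length for g in genes)
    matrix = np.full((len(taxa), total), pad, dtype=np.uint8)
    partitions: list[Partition] = []
    offset = 0
    for g in genes:
        stray = [t for t in g.taxa if t not in taxon_index]
        if stray:
            raise ValueError(f"gene {g.gene_id}: taxa not in the declared universe: {stray}")
        rows = [taxon_index[t] for t in g.taxa]
        matrix[rows, offset : offset + g.length] = g.codes
        partitions.append(Partition(g.gene_id, offset, offset + g.length))
        offset += g.length
    bundle = SupermatrixBundle(
        GeneAlignment("supermatrix", taxa, matrix), partitions, missing_char
    )
    return bundle


def write_supermatrix(
    bundle: SupermatrixBundle, fasta_path: str | Path, partition_path: str | Path
) -> None:
    """Write the supermatrix FASTA plus a RAxML-style partition file.

    Partition lines use the ``DNA, gene = start-end`` dialect with 1-based
    inclusive coordinates; the in-memory representation stays 0-based
    half-open.
    """
    if not bundle.partitions or bundle.matrix.n_taxa == 0:
        raise ValueError("refusing to write an empty supermatrix")
    with open(fasta_path, "w") as fh:
        for i, t in enumerate(bundle.taxa):
            fh.write(f">{t}\n{decode_row(bundle.matrix.codes[i])}\n")
    with open(partition_path, "w") as fh:
        for p in bundle.partitions:
            fh.write(f"DNA, {p.gene_id} = {p.start + 1}-{p.end}\n")


_PARTITION_RE = re.compile(r"^DNA,\s*(\S+)\s*=\s*(\d+)-(\d+)\s*$")


def read_supermatrix(fasta_path: str | Path, partition_path: str | Path) -> SupermatrixBundle:
    aln = read_gene_alignment(fasta_path)
    aln.gene_id = "supermatrix"
    partitions = []
    with open(partition_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            m = _PARTITION_RE.match(line.strip())
            if not m:
                raise ValueError(f"{partition_path}:{lineno}: bad partition line {line.strip()!r}")
            partitions.append(Partition(m.group(1), int(m.group(2)) - 1, int(m.group(3))))
    return SupermatrixBundle(aln, partitions)
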