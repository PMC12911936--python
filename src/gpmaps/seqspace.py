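"""Sequence spaces, genotype indexing and file I/O.

A sequence space is the set of all length-``l`` strings over an ordered
alphabet of ``alpha`` symbols. Genotypes are indexed by a mixed-radix
(base-``alpha``) encoding with the leftmost site most significant, so that
vectors over the space reshape naturally into ``l``-dimensional tensors of
shape ``(alpha,) * l`` — the layout the Kronecker-structured operators rely
on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

DNA = "ACGT"
RNA = "ACGU"
PROTEIN = "ACDEFGHIKLMNPQRSTVWY"

#: Largest number of genotypes a SequenceSpace may hold by default.
DEFAULT_MAX_GENOTYPES = 4**12

ALPHABETS = {"dna": DNA, "rna": RNA, "protein": PROTEIN}


def resolve_alphabet(name: str) -> str:
    """Resolve an alphabet name (``dna``/``rna``/``protein``) or literal
    symbol string into an ordered symbol string."""
    return ALPHABETS.get(name.lower(), name)


class SequenceSpace:
    """The space of all sequences of a fixed length over a fixed alphabet.

    Parameters
    ----------
    alphabet : str or sequence of str
        Ordered collection of unique symbols (size >= 2).
    length : int
        Sequence length ``l`` >= 1.
    max_genotypes : int
        Budget on ``alpha ** l``; the constructor refuses larger spaces.
    """

    def __init__(self, alphabet="ACGT", length: int = 1,
                 max_genotypes: int = DEFAULT_MAX_GENOTYPES):
        symbols = list(alphabet)
        if len(symbols) < 2:
            raise ValueError("alphabet must contain at least 2 symbols")
        if len(set(symbols)) != len(symbols):
            raise ValueError(f"alphabet symbols must be unique: {symbols}")
        if length < 1:
            raise ValueError("length must be >= 1")
        self.alphabet = symbols
        self.alpha = len(symbols)
        self.length = int(length)
        n = self.alpha**self.length
        if n > max_genotypes:
            raise ValueError(
                f"space of {n} genotypes exceeds the budget of {max_genotypes}"
            )
        self.n_genotypes = n
        self._sym_to_code = {s: i for i, s in enumerate(symbols)}
        # powers[p] = alpha^(l-1-p): weight of site p in the mixed radix code
        self.powers = self.alpha ** np.arange(self.length - 1, -1, -1)

    # ------------------------------------------------------------------ #
    def __repr__(self):
        a = "".join(self.alphabet)
        return f"SequenceSpace(alphabet={a!r}, length={self.length})"

    def __eq__(self, other):
        return (
            isinstance(other, SequenceSpace)
            and self.alphabet == other.alphabet
            and self.length == other.length
        )

    def __hash__(self):
        return hash((tuple(self.alphabet), self.length))

    @property
    def tensor_shape(self):
        return (self.alpha,) * self.length

    @property
    def n_edges(self):
        """Number of Hamming-graph edges: alpha^l * l * (alpha-1) / 2."""
        return self.n_genotypes * self.length * (self.alpha - 1) // 2

    # ------------------------------------------------------------------ #
    def seq_to_index(self, sequence: str) -> int:
        """Mixed-radix encode a sequence, leftmost site most significant."""
        if len(sequence) != self.length:
            raise ValueError(
                f"sequence {sequence!r} has length {len(sequence)}, "
                f"expected {self.length}"
            )
        idx = 0
        for pos, sym in enumerate(sequence):
            code = self._sym_to_code.get(sym)
            if code is None:
                raise ValueError(
                    f"unknown symbol {sym!r} at position {pos} in {sequence!r}"
                )
            idx = idx * self.alpha + code
        return idx

    def index_to_seq(self, index: int) -> str:
        if not 0 <= index < self.n_genotypes:
            raise IndexError(f"index {index} out of range [0, {self.n_genotypes})")
        out = []
        for _ in range(self.length):
            index, code = divmod(index, self.alpha)
            out.append(self.alphabet[code])
        return "".join(reversed(out))

    def seqs_to_indices(self, sequences) -> np.ndarray:
        return np.array([self.seq_to_index(s) for s in sequences], dtype=np.int64)

    def all_sequences(self):
        """All genotypes, in index order (dense-budget spaces only)."""
        return [self.index_to_seq(i) for i in range(self.n_genotypes)]

    # ------------------------------------------------------------------ #
    def hamming_neighbors(self, index: int) -> np.ndarray:
        """Indices of the l*(alpha-1) genotypes at Hamming distance 1."""
        if not 0 <= index < self.n_genotypes:
            raise IndexError(f"index {index} out of range [0, {self.n_genotypes})")
        out = np.empty(self.length * (self.alpha - 1), dtype=np.int64)
        k = 0
        for p in range(self.length):
            w = self.powers[p]
            code = (index // w) % self.alpha
            base = index - code * w
            for c in range(self.alpha):
                if c != code:
                    out[k] = base + c * w
                    k += 1
        return out

    def edge_list(self) -> np.ndarray:
        """All Hamming-graph edges as an (n_edges, 2) array with i < j.

        Vectorized over sites and ordered allele pairs: for each site p and
        codes a < b, every genotype carrying ``a`` at p pairs with its
        substitution to ``b``.
        """
        idx = np.arange(self.n_genotypes, dtype=np.int64)
        rows = []
        for p in range(self.length):
            w = int(self.powers[p])
            code = (idx // w) % self.alpha
            for a in range(self.alpha):
                carriers = idx[code == a]
                for b in range(a + 1, self.alpha):
                    rows.append(
                        np.column_stack([carriers, carriers + (b - a) * w])
                    )
        edges = np.concatenate(rows, axis=0)
        return edges[np.lexsort((edges[:, 1], edges[:, 0]))]

    def hamming_distance(self, i: int, j: int) -> int:
        si, sj = self.index_to_seq(i), self.index_to_seq(j)
        return sum(a != b for a, b in zip(si, sj))


# ---------------------------------------------------------------------- #
@dataclass
class LandscapeVector:
    """A phenotype value for every genotype of a space (a complete map)."""

    space: SequenceSpace
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.space.n_genotypes,):
            raise ValueError(
                f"landscape has {self.values.shape} values, space has "
                f"{self.space.n_genotypes} genotypes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("landscape values must all be finite")

    def __len__(self):
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sequence": self.space.all_sequences(), "y": self.values}
        )


@dataclass
class ObservedData:
    """Noisy measurements on a subset of genotypes.

    ``noise_var`` holds the known per-measurement Gaussian variance
    sigma_x^2 (zero means the value is exact).
    """

    space: SequenceSpace
    genotypes: np.ndarray
    y: np.ndarray
    noise_var: np.ndarray = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=float)
        if self.noise_var is None:
            self.noise_var = np.zeros_like(self.y)
        self.noise_var = np.asarray(self.noise_var, dtype=float)
        if len(set(self.genotypes.tolist())) != len(self.genotypes):
            raise ValueError("duplicate genotypes in observed data")
        if not (len(self.genotypes) == len(self.y) == len(self.noise_var)):
            raise ValueError("genotypes, y and noise_var must share a length")
        if np.any(self.noise_var < 0):
            raise ValueError("noise variances must be nonnegative")
        if np.any(self.genotypes < 0) or np.any(
            self.genotypes >= self.space.n_genotypes
        ):
            raise ValueError("genotype index out of range")

    def __len__(self):
        return len(self.y)

    @property
    def sequences(self):
        return [self.space.index_to_seq(i) for i in self.genotypes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sequence": self.sequences, "y": self.y, "var": self.noise_var}
        )


@dataclass
class CountData:
    """Nonnegative observation counts N_i over a sequence space."""

    space: SequenceSpace
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.space.n_genotypes,):
            raise ValueError("counts vector must cover every genotype")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() <= 0:
            raise ValueError("total count must be positive")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()


# ---------------------------------------------------------------------- #
# File I/O

def read_landscape_table(path, space: SequenceSpace,
                         merge_replicates: bool = False) -> ObservedData:
    """Read a ``sequence,y[,var]`` CSV/TSV into :class:`ObservedData`.

    Duplicated sequences raise unless ``merge_replicates`` is set, in which
    case replicate measurements are averaged and their variances pooled as
    sigma^2 / n.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"sequence": str},
                     float_precision="round_trip")
    for col in ("sequence", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    bad = df.index[df["y"].isna()]
    if len(bad):
        raise ValueError(f"{path}: malformed y value at data line {bad[0] + 2}")
    if "var" not in df.columns:
        df["var"] = 0.0

    if df["sequence"].duplicated().any():
        if not merge_replicates:
            dup = df["sequence"][df["sequence"].duplicated()].iloc[0]
            raise ValueError(
                f"{path}: duplicated sequence {dup!r} "
                "(pass merge_replicates=True to average)"
            )
        grouped = df.groupby("sequence", sort=False)
        df = pd.DataFrame(
            {
                "sequence": list(grouped.groups),
                "y": grouped["y"].mean().values,
                "var": (grouped["var"].mean() / grouped.size()).values,
            }
        )

    idx = space.seqs_to_indices(df["sequence"])
    return ObservedData(space, idx, df["y"].values, df["var"].values)


def write_landscape_table(data, path):
    """Write an ObservedData or LandscapeVector as a sequence,y[,var] CSV.

    Floats are written with 17 significant digits so a read round-trips to
    the exact binary value.
    """
    data.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_counts_table(path, space: SequenceSpace) -> CountData:
    """Read a ``sequence,count`` CSV into a dense :class:`CountData`."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"sequence": str})
    counts = np.zeros(space.n_genotypes, dtype=np.int64)
    for seq, n in zip(df["sequence"], df["count"]):
        counts[space.seq_to_index(seq)] += int(n)
    return CountData(space, counts)


def write_counts_table(data: CountData, path):
    nz = np.flatnonzero(data.counts)
    pd.DataFrame(
        {
            "sequence": [data.space.index_to_seq(i) for i in nz],
            "count": data.counts[nz],
        }
    ).to_csv(path, index=False)


def counts_from_fasta(path, space: SequenceSpace, strict: bool = False,
                      normalize_u_t: bool = False) -> CountData:
    """Tally fixed-length FASTA records into per-genotype counts.

    Records of the wrong length or with symbols outside the alphabet are
    skipped with a warning (or raise under ``strict``). ``normalize_u_t``
    maps U<->T to match the configured alphabet before tallying.
    """
    counts = np.zeros(space.n_genotypes, dtype=np.int64)
    n_skipped = 0
    trans = None
    if normalize_u_t:
        # map toward whichever of U/T the configured alphabet uses
        trans = (str.maketrans("Tt", "UU") if "U" in space.alphabet
                 else str.maketrans("Uu", "TT"))
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if trans is not None:
            seq = seq.translate(trans)
        try:
            counts[space.seq_to_index(seq)] += 1
        except (ValueError, IndexError) as err:
            if strict:
                raise ValueError(f"{path}: record {rec.id}: {err}") from err
            n_skipped += 1
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} unparseable records")
    return CountData(space, counts)
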