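"""Multi-scale local descriptor (MLD) featurization of protein sequences.

A protein sequence is mapped onto a reduced seven-letter alphabet (amino
acids grouped by side-chain dipole and volume), the sequence is cut into S
equal-length segments, and every *continuous region* — a contiguous run of
segments, selected by a binary mask such as ``0011`` (= the final half of
the chain) — is summarised by the classical composition / transition /
distribution (CTD) descriptors:

* composition (7 values): percentage of residues in each group;
* transition (21 values): for each unordered group pair, the percentage of
  adjacent residue pairs that alternate between the two groups;
* distribution (35 values): for each group, the relative chain position of
  its first, 25%, 50%, 75% and 100% occurrence.

With S = 4 segments there are 9 continuous regions (the 10 contiguous masks
minus the full-length one), hence 9 × 63 = 567 features per protein and
1134 per protein pair (concatenation of both partners).

All percentages are on the 0–100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .sequence_io import ProteinRecord

#: Layout identifier written into feature sidecars and model artifacts; bump
#: whenever the mask order, descriptor order or grouping changes.
LAYOUT_VERSION = "mld-ctd-7g-v1"

N_GROUPS = 7

#: The seven physicochemical groups (side-chain dipole and volume).
GROUP_RESIDUES: tuple[str, ...] = ("AGV", "C", "MSTY", "FILP", "HNQW", "KR", "DE")

#: Amino acid -> group index in 1..7.
SEVEN_GROUP_ALPHABET: Mapping[str, int] = {
    aa: g for g, residues in enumerate(GROUP_RESIDUES, start=1) for aa in residues
}

#: Fixed ordering of the 21 unordered group pairs for the transition block.
TRANSITION_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (g, h) for g in range(1, N_GROUPS + 1) for h in range(g + 1, N_GROUPS + 1)
)

#: Distribution milestones: first occurrence, then the 25/50/75/100% quantile
#: occurrences (quantile index = max(1, floor(q * n)) for n occurrences).
DISTRIBUTION_QUARTERS = (1, 2, 3, 4)

DESCRIPTORS_PER_REGION = N_GROUPS + len(TRANSITION_PAIRS) + N_GROUPS * 5  # 63


class EncodingError(ValueError):
    """Sequence cannot be encoded under the given configuration."""


@dataclass(frozen=True)
class EncoderConfig:
    """Parameters of the multi-scale local descriptor encoder.

    Attributes
    ----------
    n_segments
        Number S of equal-length segments (2..8). S = 4 gives the standard
        567-dimensional per-protein layout.
    include_full
        Whether to also include the full-length (all-ones) mask as a region.
        Off by default; the standard layout uses the 9 proper regions.
    min_length
        Minimum residue count a protein must have to enter a dataset
        (curation rule; the encoder itself only needs length >= n_segments).
    ambiguity_policy
        Forwarded to :func:`mldppi.sequence_io.read_fasta`.
    """

    n_segments: int = 4
    include_full: bool = False
    min_length: int = 50
    ambiguity_policy: str = "skip_record"

    def __post_init__(self) -> None:
        if not 2 <= self.n_segments <= 8:
            raise ValueError(f"n_segments must be in 2..8, got {self.n_segments}")

    @property
    def region_count(self) -> int:
        n = self.n_segments
        return n * (n + 1) // 2 - (0 if self.include_full else 1)

    @property
    def protein_dim(self) -> int:
        return DESCRIPTORS_PER_REGION * self.region_count

    @property
    def pair_dim(self) -> int:
        return 2 * self.protein_dim


@dataclass(frozen=True)
class RegionMask:
    """Binary mask over S segments whose set bits form one contiguous run."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        ones = [i for i, b in enumerate(self.bits) if b == 1]
        if not ones or any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"invalid region mask {self.bits}")
        if ones != list(range(ones[0], ones[-1] + 1)):
            raise ValueError(f"region mask {self.bits} is not contiguous")

    @property
    def first_segment(self) -> int:
        return self.bits.index(1)

    @property
    def last_segment(self) -> int:
        return len(self.bits) - 1 - self.bits[::-1].index(1)

    def __str__(self) -> str:
        return "".join(map(str, self.bits))


def group_encode(
    seq: str, alphabet: Mapping[str, int] = SEVEN_GROUP_ALPHABET
) -> np.ndarray:
    """Map an amino-acid string to its group-index sequence (values 1..7).

    >>> "".join(map(str, group_encode("GGYCCCYYGYYYGCCGGYYGCG")))
    '1132223313331221133121'
    """
    table = np.zeros(128, dtype=np.int8)
    for aa, g in alphabet.items():
        table[ord(aa)] = g
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = table[raw]
    if (codes == 0).any():
        pos = int(np.flatnonzero(codes == 0)[0])
        raise EncodingError(
            f"unmapped character {seq[pos]!r} at position {pos + 1}"
        )
    return codes


@lru_cache(maxsize=None)
def build_region_masks(n_segments: int, include_full: bool = False) -> tuple[RegionMask, ...]:
    """Enumerate all contiguous-run masks over *n_segments* segments.

    Masks are ordered by run length ascending, then run start ascending
    (for S=4: 1000, 0100, 0010, 0001, 1100, 0110, 0011, 1110, 0111). The
    all-ones mask is excluded unless *include_full*; the count is then
    n(n+1)/2 − 1.
    """
    if not 2 <= n_segments <= 8:
        raise ValueError(f"n_segments must be in 2..8, got {n_segments}")
    max_run = n_segments if include_full else n_segments - 1
    masks = []
    for run in range(1, max_run + 1):
        for start in range(n_segments - run + 1):
            bits = tuple(1 if start <= i < start + run else 0 for i in range(n_segments))
            masks.append(RegionMask(bits))
    return tuple(masks)


def n_binary_region_codes(n_segments: int) -> int:
    """Count of all non-degenerate binary segment codes, 2**S − 2.

    This counts every mask except all-zero and all-one, including
    discontinuous ones; only the contiguous subset is used for features.
    """
    return 2 ** n_segments - 2


def segment_boundaries(length: int, n_segments: int) -> list[tuple[int, int]]:
    """Partition positions 1..length into *n_segments* equal-length intervals.

    Segment k covers floor((k−1)·L/n)+1 .. floor(k·L/n), 1-based inclusive;
    the intervals are non-empty and tile 1..L exactly.
    """
    if length < n_segments:
        raise EncodingError(
            f"sequence of length {length} too short for {n_segments} segments"
        )
    return [
        (((k - 1) * length) // n_segments + 1, (k * length) // n_segments)
        for k in range(1, n_segments + 1)
    ]


def extract_region(
    codes: np.ndarray, mask: RegionMask, boundaries: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Slice the contiguous sub-sequence selected by *mask*."""
    if len(mask.bits) != len(boundaries):
        raise ValueError(
            f"mask width {len(mask.bits)} != number of segments {len(boundaries)}"
        )
    start = boundaries[mask.first_segment][0]
    end = boundaries[mask.last_segment][1]
    return codes[start - 1 : end]


def composition(region: np.ndarray) -> np.ndarray:
    """Per-group residue percentages (7 values summing to 100)."""
    if region.size == 0:
        raise EncodingError("composition of an empty region is undefined")
    counts = np.bincount(region, minlength=N_GROUPS + 1)[1:]
    return 100.0 * counts / region.size


def transition(region: np.ndarray) -> np.ndarray:
    """Alternation percentages for the 21 unordered group pairs.

    For pair (g, h) this is 100 × (number of adjacent positions whose codes
    are g,h or h,g) / (region length − 1). A length-1 region has no
    adjacencies and yields all zeros.
    """
    if region.size == 0:
        raise EncodingError("transition of an empty region is undefined")
    out = np.zeros(len(TRANSITION_PAIRS))
    if region.size < 2:
        return out
    a, b = region[:-1], region[1:]
    counts = np.zeros((N_GROUPS + 1, N_GROUPS + 1), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    denom = region.size - 1
    for i, (g, h) in enumerate(TRANSITION_PAIRS):
        out[i] = 100.0 * (counts[g, h] + counts[h, g]) / denom
    return out


def distribution(region: np.ndarray) -> np.ndarray:
    """Occurrence-quantile positions for each group (35 values).

    For a group with occurrences at 1-based region positions p_1 < … < p_n,
    the five values are 100 · p_i / L at i = 1 and i = max(1, floor(q·n))
    for q = 25%, 50%, 75%, 100%. A group absent from the region yields five
    zeros.
    """
    if region.size == 0:
        raise EncodingError("distribution of an empty region is undefined")
    L = region.size
    out = np.zeros(N_GROUPS * 5)
    for g in range(1, N_GROUPS + 1):
        pos = np.flatnonzero(region == g) + 1  # 1-based
        n = pos.size
        if n == 0:
            continue
        # integer arithmetic keeps floor(q*n) exact for q in quarters
        idx = [1] + [max(1, (k * n) // 4) for k in DISTRIBUTION_QUARTERS]
        out[(g - 1) * 5 : g * 5] = 100.0 * pos[np.array(idx) - 1] / L
    return out


def ctd_descriptor(region: np.ndarray) -> np.ndarray:
    """The 63 CTD values for one region, ordered [C(7), T(21), D(35)]."""
    return np.concatenate([composition(region), transition(region), distribution(region)])


def encode_protein(
    record: ProteinRecord | str, config: EncoderConfig = EncoderConfig()
) -> np.ndarray:
    """Full multi-scale feature vector for one protein.

    Concatenates the 63-value CTD descriptor of every continuous region in
    :func:`build_region_masks` order; 567 values under the default S=4
    layout. Deterministic: identical sequence and config give bit-identical
    output.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    codes = group_encode(seq)
    boundaries = segment_boundaries(len(seq), config.n_segments)
    masks = build_region_masks(config.n_segments, config.include_full)
    return np.concatenate(
        [ctd_descriptor(extract_region(codes, m, boundaries)) for m in masks]
    )


def encode_pair(vec_a: np.ndarray, vec_b: np.ndarray) -> np.ndarray:
    """Pair feature vector: protein A's vector followed by protein B's."""
    if vec_a.shape != vec_b.shape or vec_a.ndim != 1:
        raise ValueError(
            f"protein vectors must be 1-D and same-dimensional, got {vec_a.shape} vs {vec_b.shape}"
        )
    return np.concatenate([vec_a, vec_b])


def pair_feature_matrix(
    records: Sequence[ProteinRecord],
    pairs: Sequence,
    config: EncoderConfig = EncoderConfig(),
    augment_swapped: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a labelled pair list into a feature matrix and label vector.

    Each protein is encoded once and cached. Pair features follow the pair
    file's protein order; with *augment_swapped* every pair additionally
    contributes its swapped orientation as a second row.
    """
    by_id = {r.id: r for r in records}
    cache: dict[str, np.ndarray] = {}

    def vec(pid: str) -> np.ndarray:
        if pid not in cache:
            cache[pid] = encode_protein(by_id[pid], config)
        return cache[pid]

    rows, labels = [], []
    for p in pairs:
        rows.append(encode_pair(vec(p.id_a), vec(p.id_b)))
        labels.append(p.label)
        if augment_swapped:
            rows.append(encode_pair(vec(p.id_b), vec(p.id_a)))
            labels.append(p.label)
    X = np.vstack(rows) if rows else np.empty((0, config.pair_dim))
    return X, np.asarray(labels, dtype=int)


def feature_names(config: EncoderConfig = EncoderConfig()) -> list[str]:
    """Column names for one protein's feature vector (layout documentation)."""
    names = []
    for mask in build_region_masks(config.n_segments, config.include_full):
        prefix = f"r{mask}"
        names += [f"{prefix}_C_g{g}" for g in range(1, N_GROUPS + 1)]
        names += [f"{prefix}_T_g{g}g{h}" for g, h in TRANSITION_PAIRS]
        names += [
            f"{prefix}_D_g{g}_{m}"
            for g in range(1, N_GROUPS + 1)
            for m in ("first", "q25", "q50", "q75", "q100")
        ]
    return names
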