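"""Sequence encodings for 41-nt adenine-centred DNA windows.

Six encodings turn a window into a fixed-length numeric feature row:

``NUM`` (40)
    Each flanking nucleotide mapped alphabetically to a scalar,
    A=0.25, C=0.50, G=0.75, T=1.0; the central adenine is constant and
    therefore omitted.
``MBE`` (164)
    Mononucleotide binary encoding: per-position one-hot over
    (A, C, G, T), all 41 positions included.
``DBE_LPF`` (200)
    Dinucleotide binary encoding (160): each of the 40 overlapping
    dinucleotides as the 4-bit code of its index under letter order
    A, T, C, G for both letters (AA=0000, AT=0001, AC=0010, ..., GG=1111);
    plus the local position-specific dinucleotide frequency (40): for
    j = 2..41, the count of the dinucleotide ending at position j among
    the dinucleotides of the length-j prefix, divided by j.
``RFHC`` (164)
    Ring/function/hydrogen chemical properties plus cumulative density:
    per position the triple a=1 iff purine {A,G} (one ring class),
    b=1 iff weak pairing {A,T} (two hydrogen bonds), c=1 iff amino
    group {A,C}, so A=(1,1,1), C=(0,0,1), G=(1,0,0), T=(0,1,0); and
    d_i = frequency of the position-i base within the first i bases.
``KNN`` (7)
    For n in (2, 4, 8, 16, 32, 64, 128), the fraction of positive-labeled
    sequences among the n most similar reference windows, similarity
    being +2 per matching position and -1 per mismatch.
``KMER`` (1364)
    Concatenated mono- to penta-nucleotide composition blocks
    (4 + 16 + 64 + 256 + 1024), each block a frequency vector summing
    to one.

All encoders are pure functions of their inputs; the KNN encoding
additionally depends on an immutable labeled reference snapshot built
from training data only (see :func:`build_knn_reference`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np

from .seqio import (
    CENTER_INDEX,
    WINDOW_LENGTH,
    LabeledDataset,
    SequenceRecord,
    WindowValidationError,
    validate_window,
)

__all__ = [
    "ENCODING_DIMS",
    "DEFAULT_ENCODINGS",
    "KNN_N_VALUES",
    "FeatureMatrix",
    "KnnReference",
    "encode_num",
    "encode_mbe",
    "encode_dbe",
    "encode_lpf",
    "encode_dbe_lpf",
    "encode_rfhc",
    "encode_kmer",
    "encode_knn",
    "similarity_score",
    "build_knn_reference",
    "encode_records",
    "encode_dataset",
    "feature_names",
]

# Alphabetical nucleotide order used by NUM, MBE, RFHC density and KMER.
_ACGT = "ACGT"
_CODE = {b: i for i, b in enumerate(_ACGT)}

# DBE letter order: the printed example codes AA=0000, AT=0001, AC=0010
# force second-letter order A, T, C, ...; the same order is used for both
# letters, giving AG=0011, TA=0100, ..., GG=1111.
_DBE_ORDER = {b: i for i, b in enumerate("ATCG")}

KNN_N_VALUES: tuple[int, ...] = (2, 4, 8, 16, 32, 64, 128)

#: Feature dimension per encoding.
ENCODING_DIMS = {
    "NUM": 40,
    "MBE": 164,
    "DBE": 160,
    "LPF": 40,
    "DBE_LPF": 200,
    "RFHC": 164,
    "KNN": 7,
    "KMER": 1364,
}

#: The five encodings retained in the final predictor.
DEFAULT_ENCODINGS: tuple[str, ...] = ("NUM", "MBE", "DBE_LPF", "RFHC", "KNN")

# RFHC chemical-property coordinates (a, b, c) per base.
_RFHC_ABC = {
    "A": (1.0, 1.0, 1.0),
    "C": (0.0, 0.0, 1.0),
    "G": (1.0, 0.0, 0.0),
    "T": (0.0, 1.0, 0.0),
}


def _seq_of(rec: SequenceRecord | str) -> str:
    seq = rec.seq if isinstance(rec, SequenceRecord) else rec
    ok, reason = validate_window(seq)
    if not ok:
        rid = rec.id if isinstance(rec, SequenceRecord) else "<str>"
        raise WindowValidationError(f"record {rid!r}: {reason}")
    return seq


def _codes(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[b] for b in seq), dtype=np.int8, count=len(seq))


@dataclass
class FeatureMatrix:
    """One encoding's feature rows for a set of records."""

    encoding_name: str
    values: np.ndarray  # (n_records, dim) float64
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        expected = ENCODING_DIMS.get(self.encoding_name)
        if expected is not None and self.values.shape[1] != expected:
            raise ValueError(
                f"{self.encoding_name}: expected {expected} features, "
                f"got {self.values.shape[1]}"
            )

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path, ids: Optional[Sequence[str]] = None) -> None:
        """Write the matrix as TSV with a header row naming features."""
        names = self.names or feature_names(self.encoding_name)
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(names) + "\n")
            for i, row in enumerate(self.values):
                rid = ids[i] if ids is not None else str(i)
                fh.write(rid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def encode_num(rec: SequenceRecord | str) -> np.ndarray:
    """Numerical representation of the 40 flanking nucleotides."""
    seq = _seq_of(rec)
    mapping = {"A": 0.25, "C": 0.50, "G": 0.75, "T": 1.0}
    vals = [mapping[b] for i, b in enumerate(seq) if i != CENTER_INDEX]
    return np.asarray(vals, dtype=float)


def encode_mbe(rec: SequenceRecord | str) -> np.ndarray:
    """Per-position one-hot encoding over (A, C, G, T), all 41 positions."""
    seq = _seq_of(rec)
    out = np.zeros((WINDOW_LENGTH, 4), dtype=float)
    out[np.arange(WINDOW_LENGTH), _codes(seq)] = 1.0
    return out.ravel()


def _dbe_index(dinuc: str) -> int:
    return 4 * _DBE_ORDER[dinuc[0]] + _DBE_ORDER[dinuc[1]]


def encode_dbe(rec: SequenceRecord | str) -> np.ndarray:
    """4-bit binary code per overlapping dinucleotide (40 x 4 = 160)."""
    seq = _seq_of(rec)
    out = np.empty((WINDOW_LENGTH - 1, 4), dtype=float)
    for j in range(WINDOW_LENGTH - 1):
        idx = _dbe_index(seq[j : j + 2])
        out[j] = [(idx >> 3) & 1, (idx >> 2) & 1, (idx >> 1) & 1, idx & 1]
    return out.ravel()


def encode_lpf(rec: SequenceRecord | str) -> np.ndarray:
    """Local position-specific dinucleotide frequency.

    For each position j = 2..41 (1-based), the number of occurrences of
    the dinucleotide ending at j among the dinucleotides of the
    length-j prefix, divided by the prefix length j.  The first value is
    always 1/2 and every value lies in (0, 1].
    """
    seq = _seq_of(rec)
    counts: dict[str, int] = {}
    out = np.empty(WINDOW_LENGTH - 1, dtype=float)
    for j in range(1, WINDOW_LENGTH):  # 0-based end of dinucleotide
        dinuc = seq[j - 1 : j + 1]
        counts[dinuc] = counts.get(dinuc, 0) + 1
        out[j - 1] = counts[dinuc] / (j + 1)
    return out


def encode_dbe_lpf(rec: SequenceRecord | str) -> np.ndarray:
    """Concatenated dinucleotide binary code and local frequency (200)."""
    return np.concatenate([encode_dbe(rec), encode_lpf(rec)])


def encode_rfhc(rec: SequenceRecord | str) -> np.ndarray:
    """Chemical-property triple plus cumulative nucleotide density (164)."""
    seq = _seq_of(rec)
    out = np.empty((WINDOW_LENGTH, 4), dtype=float)
    seen: dict[str, int] = {}
    for i, b in enumerate(seq):
        seen[b] = seen.get(b, 0) + 1
        a, h, c = _RFHC_ABC[b]
        out[i] = (a, h, c, seen[b] / (i + 1))
    return out.ravel()


def encode_kmer(rec: SequenceRecord | str) -> np.ndarray:
    """Mono- through penta-nucleotide composition (4+16+64+256+1024)."""
    seq = _seq_of(rec)
    codes = _codes(seq)
    blocks: list[np.ndarray] = []
    for k in range(1, 6):
        n_kmers = WINDOW_LENGTH - k + 1
        idx = np.zeros(n_kmers, dtype=np.int64)
        for off in range(k):
            idx = idx * 4 + codes[off : off + n_kmers]
        block = np.bincount(idx, minlength=4**k).astype(float) / n_kmers
        blocks.append(block)
    return np.concatenate(blocks)


def similarity_score(p1: str, p2: str) -> int:
    """Positional similarity: +2 per matching base, -1 per mismatch."""
    if len(p1) != len(p2):
        raise ValueError(f"length mismatch: {len(p1)} vs {len(p2)}")
    matches = sum(a == b for a, b in zip(p1, p2))
    return 3 * matches - len(p1)


@dataclass(frozen=True)
class KnnReference:
    """Immutable labeled snapshot used by the KNN encoding.

    Built from training data only; rebuilding it per cross-validation
    fold (and excluding the query's own record) is what keeps the KNN
    features leakage-free.
    """

    codes: np.ndarray  # (n_ref, 41) int8, read-only
    labels: np.ndarray  # (n_ref,) int
    ids: tuple[str, ...]
    n_values: tuple[int, ...] = KNN_N_VALUES

    def __post_init__(self) -> None:
        self.codes.setflags(write=False)
        self.labels.setflags(write=False)

    @property
    def n_ref(self) -> int:
        return self.codes.shape[0]


def build_knn_reference(train: LabeledDataset) -> KnnReference:
    """Snapshot a labeled training set for KNN encoding.

    Requires at least ``max(n_values)`` labeled records so the largest
    neighbourhood is well defined.
    """
    labels = train.labels()
    if len(train) < max(KNN_N_VALUES):
        raise ValueError(
            f"KNN reference needs >= {max(KNN_N_VALUES)} labeled records, "
            f"got {len(train)}"
        )
    codes = np.stack([_codes(r.seq) for r in train.records])
    return KnnReference(codes=codes, labels=labels, ids=tuple(train.ids()))


def _similarity_matrix(qcodes: np.ndarray, rcodes: np.ndarray) -> np.ndarray:
    """Pairwise +2/-1 similarity scores, (n_query, n_ref) int16."""
    out = np.empty((qcodes.shape[0], rcodes.shape[0]), dtype=np.int16)
    block = max(1, 2**20 // max(1, rcodes.shape[0]))  # bound peak memory
    for start in range(0, qcodes.shape[0], block):
        q = qcodes[start : start + block]
        matches = (q[:, None, :] == rcodes[None, :, :]).sum(axis=2)
        out[start : start + block] = 3 * matches - qcodes.shape[1]
    return out


def _knn_features_from_sims(
    sims: np.ndarray, ref: KnnReference, excluded: np.ndarray
) -> np.ndarray:
    """Turn a similarity matrix into per-query positive fractions.

    ``excluded`` is a boolean (n_query, n_ref) mask of reference entries
    removed before ranking (self matches).  Ties in similarity are broken
    by reference insertion order, which the stable sort preserves.
    """
    n_query, n_ref = sims.shape
    usable = n_ref - excluded.sum(axis=1)
    if np.any(usable < max(ref.n_values)):
        raise ValueError(
            "KNN reference too small after self-exclusion for the largest "
            f"neighbourhood (need {max(ref.n_values)})"
        )
    work = sims.astype(np.int32)
    # Push excluded entries below any attainable score so they sort last.
    work[excluded] = np.iinfo(np.int16).min
    order = np.argsort(-work, axis=1, kind="stable")
    pos_sorted = ref.labels[order]
    cum = np.cumsum(pos_sorted, axis=1)
    feats = np.empty((n_query, len(ref.n_values)), dtype=float)
    for col, n in enumerate(ref.n_values):
        feats[:, col] = cum[:, n - 1] / n
    return feats


def _exclusion_mask(ids: Sequence[str], ref: KnnReference) -> np.ndarray:
    ref_index: dict[str, list[int]] = {}
    for j, rid in enumerate(ref.ids):
        ref_index.setdefault(rid, []).append(j)
    mask = np.zeros((len(ids), ref.n_ref), dtype=bool)
    for i, qid in enumerate(ids):
        for j in ref_index.get(qid, ()):
            mask[i, j] = True
    return mask


def encode_knn_batch(
    records: Sequence[SequenceRecord],
    ref: KnnReference,
    exclude_self: bool = False,
) -> np.ndarray:
    """KNN features for many records at once (vectorised).

    With ``exclude_self`` any reference entry carrying the same record id
    as the query is dropped before ranking, so a training record never
    counts itself among its own neighbours.
    """
    qcodes = np.stack([_codes(_seq_of(r)) for r in records])
    sims = _similarity_matrix(qcodes, ref.codes)
    if exclude_self:
        ids = [r.id if isinstance(r, SequenceRecord) else "" for r in records]
        excluded = _exclusion_mask(ids, ref)
    else:
        excluded = np.zeros(sims.shape, dtype=bool)
    return _knn_features_from_sims(sims, ref, excluded)


def encode_knn(
    rec: SequenceRecord | str, ref: KnnReference, exclude_self: bool = False
) -> np.ndarray:
    """KNN feature row (7 positive fractions) for one record."""
    if isinstance(rec, str):
        rec = SequenceRecord(id="", seq=rec)
    return encode_knn_batch([rec], ref, exclude_self=exclude_self)[0]


_SINGLE_ENCODERS = {
    "NUM": encode_num,
    "MBE": encode_mbe,
    "DBE": encode_dbe,
    "LPF": encode_lpf,
    "DBE_LPF": encode_dbe_lpf,
    "RFHC": encode_rfhc,
    "KMER": encode_kmer,
}


def encode_records(
    records: Sequence[SequenceRecord],
    encoding: str,
    ref: Optional[KnnReference] = None,
    exclude_self: bool = False,
) -> FeatureMatrix:
    """Encode records under one named encoding into a :class:`FeatureMatrix`."""
    encoding = encoding.upper()
    if encoding == "KNN":
        if ref is None:
            raise ValueError("KNN encoding requires a reference (build_knn_reference)")
        values = encode_knn_batch(records, ref, exclude_self=exclude_self)
    elif encoding in _SINGLE_ENCODERS:
        fn = _SINGLE_ENCODERS[encoding]
        values = np.stack([fn(r) for r in records])
    else:
        raise KeyError(f"unknown encoding {encoding!r}; known: {sorted(ENCODING_DIMS)}")
    return FeatureMatrix(encoding_name=encoding, values=values, names=feature_names(encoding))


def encode_dataset(
    dataset: LabeledDataset,
    encoding: str,
    ref: Optional[KnnReference] = None,
    exclude_self: bool = False,
) -> FeatureMatrix:
    return encode_records(dataset.records, encoding, ref=ref, exclude_self=exclude_self)


def feature_names(encoding: str) -> list[str]:
    """Human-readable column names for one encoding (TSV export)."""
    encoding = encoding.upper()
    if encoding == "NUM":
        positions = [p for p in range(1, WINDOW_LENGTH + 1) if p != CENTER_INDEX + 1]
        return [f"NUM_pos{p:02d}" for p in positions]
    if encoding == "MBE":
        return [
            f"MBE_pos{p:02d}_{b}" for p in range(1, WINDOW_LENGTH + 1) for b in _ACGT
        ]
    if encoding == "DBE":
        return [
            f"DBE_din{j:02d}_b{k}" for j in range(1, WINDOW_LENGTH) for k in range(4)
        ]
    if encoding == "LPF":
        return [f"LPF_pos{j:02d}" for j in range(2, WINDOW_LENGTH + 1)]
    if encoding == "DBE_LPF":
        return feature_names("DBE") + feature_names("LPF")
    if encoding == "RFHC":
        return [
            f"RFHC_pos{p:02d}_{c}"
            for p in range(1, WINDOW_LENGTH + 1)
            for c in ("ring", "hbond", "amino", "density")
        ]
    if encoding == "KNN":
        return [f"KNN_n{n}" for n in KNN_N_VALUES]
    if encoding == "KMER":
        names: list[str] = []
        for k in range(1, 6):
            names.extend("KMER_" + "".join(t) for t in product(_ACGT, repeat=k))
        return names
    raise KeyError(f"unknown encoding {encoding!r}")
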