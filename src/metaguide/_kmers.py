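"""Low-level k-mer machinery shared across the package.

Sequences are handled as ``uint8`` code arrays (A=0, C=1, G=2, T=3, anything
else = 4).  K-mers are packed 2 bits/base into ``uint64`` (valid for k <= 31);
windows containing a non-ACGT base are masked out.  Canonical form is the
lexicographic minimum of a k-mer and its reverse complement, which under the
A<C<G<T encoding equals the numeric minimum of the packed codes.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

#: default seed for the recorded 64-bit hash; stored in database manifests.
DEFAULT_HASH_SEED = 42


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def decode(codes: np.ndarray) -> str:
    return _BASES[np.minimum(codes, 4)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed forward k-mer codes at every start position, plus validity mask.

    Returns ``(kmers, valid)`` with ``len == len(codes) - k + 1`` (empty when
    the sequence is shorter than k).
    """
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    m = n - k + 1
    out = np.zeros(m, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    for j in range(k):
        out <<= np.uint64(2)
        out |= np.minimum(c64[j : j + m], np.uint64(3))
    bad = np.concatenate(([0], np.cumsum(codes > 3)))
    valid = (bad[k:] - bad[:-k]) == 0
    return out, valid


def canonical_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-min) packed codes of all valid k-mers, in order."""
    fwd, valid = kmer_codes(codes, k)
    if len(fwd) == 0:
        return fwd
    rc, _ = kmer_codes(revcomp_codes(codes), k)
    rc = rc[::-1]
    return np.minimum(fwd, rc)[valid]


def hash64(values: np.ndarray, seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """Vectorised splitmix64 finaliser with a recorded seed."""
    with np.errstate(over="ignore"):
        z = values.astype(np.uint64) + np.uint64(0x9E3779B97F4B7C15) * np.uint64(seed + 1)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


def _concat_codes(seqs) -> np.ndarray:
    """Concatenate sequences with single invalid-code separators.

    K-mer windows crossing a boundary contain the separator and are masked
    out, so k-mer extraction over the concatenation equals the union over the
    individual sequences.
    """
    sep = np.array([4], dtype=np.uint8)
    parts = []
    for x in seqs:
        parts.append(encode(x) if isinstance(x, str) else x)
        parts.append(sep)
    if not parts:
        return np.empty(0, dtype=np.uint8)
    return np.concatenate(parts[:-1])


def sketch_hashes(seqs, k: int, s: int, seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """Bottom-s MinHash: the s smallest distinct hashes of canonical k-mers."""
    codes = canonical_kmer_codes(_concat_codes(seqs), k)
    if len(codes) == 0:
        return np.empty(0, dtype=np.uint64)
    return np.unique(hash64(codes, seed))[:s]


def kmer_code_set(seqs, k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes of one or more sequences."""
    codes = canonical_kmer_codes(_concat_codes(seqs), k)
    if len(codes) == 0:
        return np.empty(0, dtype=np.uint64)
    return np.unique(codes)


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for j in range(k - 1, -1, -1):
        out.append("ACGT"[(int(code) >> (2 * j)) & 3])
    return "".join(out)
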