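"""Amino-acid alphabet utilities, substitution scores and biochemical
dissimilarities shared across the package.

The canonical alphabet is the 20 standard residues in alphabetical
one-letter order.  All Potts-model arrays, one-hot encodings and
mutational-effect matrices index residues in this order.
"""

from __future__ import annotations

import functools

import numpy as np
from Bio.Align import substitution_matrices

ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
A: int = len(ALPHABET)
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string as an int array over the 20-letter alphabet.

    Raises ``ValueError`` naming the first offending character if the
    sequence contains anything outside the standard residues.
    """
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        try:
            out[i] = AA_INDEX[ch]
        except KeyError:
            raise ValueError(f"invalid residue symbol {ch!r} at position {i + 1}") from None
    return out


def decode(idx: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in idx)


@functools.lru_cache(maxsize=None)
def blosum62() -> np.ndarray:
    """BLOSUM62 as a dense 20x20 array in canonical alphabet order."""
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((A, A))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = m[a, b]
    return out


# Physicochemical descriptors used to build the packaged biochemical
# dissimilarity table: Kyte-Doolittle hydropathy, van-der-Waals side-chain
# volume (A^3), net charge at physiological pH, polarity and aromaticity
# indicator variables.
_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}
_CHARGE = {aa: 0.0 for aa in ALPHABET}
_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1})
_POLAR = {aa: 1.0 if aa in "RNDQEHKSTYC" else 0.0 for aa in ALPHABET}
_AROMATIC = {aa: 1.0 if aa in "FWYH" else 0.0 for aa in ALPHABET}


@functools.lru_cache(maxsize=None)
def biochemical_dissimilarity() -> np.ndarray:
    """Synthetic 20x20 biochemical dissimilarity table.

    A property-derived stand-in for Sneath's (1966) index of average
    biochemical difference between amino-acid pairs, whose original table
    is not bundled here.  Each residue is described by standardized
    hydropathy, side-chain volume, charge, polarity and aromaticity;
    dissimilarity is the Euclidean distance between descriptor vectors,
    rescaled so the largest pair distance is 1.  Zero on the diagonal,
    symmetric, every 20x20 pair defined.
    """
    props = np.array(
        [
            [_HYDROPATHY[a], _VOLUME[a], _CHARGE[a], _POLAR[a], _AROMATIC[a]]
            for a in ALPHABET
        ]
    )
    z = (props - props.mean(axis=0)) / props.std(axis=0)
    diff = z[:, None, :] - z[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return d / d.max()
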