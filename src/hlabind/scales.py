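"""Physicochemical property scales for the 20 standard amino acids.

Five factor-analytic summaries of amino-acid physicochemistry (Atchley et
al., PNAS 2005) are shipped with the package, one column per property:

* ``CD`` — codon diversity (factor IV),
* ``EC`` — electrostatic charge (factor V),
* ``MV`` — molecular volume / size (factor III),
* ``2nd_stru`` — secondary-structure propensity (factor II),
* ``polarity`` — polarity / hydrophobicity (factor I).

Each scale is re-standardized to mean 0 and standard deviation 1 over the
20 residues before use, so squared scale differences are comparable across
properties. User-supplied scales go through the same standardization.
"""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids in alphabetical single-letter order. This
#: order fixes the component order of every composition vector.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: Property block order used throughout the feature space.
PROPERTY_NAMES: tuple[str, ...] = ("CD", "EC", "MV", "2nd_stru", "polarity")

# Atchley factor scores, rows in ALPHABET order, columns = factors I..V.
_ATCHLEY = {
    #      I       II      III     IV      V
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}

# Map property name -> Atchley factor column (0-based).
_FACTOR_OF = {"polarity": 0, "2nd_stru": 1, "MV": 2, "CD": 3, "EC": 4}


class PropertyScale:
    """A named amino-acid property scale standardized over the 20 residues.

    Parameters
    ----------
    name : str
        Scale identifier (one of :data:`PROPERTY_NAMES` for the built-ins,
        arbitrary for user scales).
    values : dict[str, float]
        Raw value for each of the 20 standard residues. Standardization to
        mean 0 / sd 1 (population sd, n = 20) happens here.
    """

    def __init__(self, name: str, values: dict[str, float]):
        if set(values) != set(ALPHABET):
            missing = sorted(set(ALPHABET) - set(values))
            extra = sorted(set(values) - set(ALPHABET))
            raise ValueError(
                f"scale {name!r} must cover exactly the 20 standard residues "
                f"(missing {missing}, unexpected {extra})"
            )
        self.name = name
        raw = np.array([values[a] for a in ALPHABET], dtype=float)
        sd = raw.std()  # population sd over the 20 residues
        if sd == 0:
            raise ValueError(f"scale {name!r} is constant; cannot standardize")
        self._h = (raw - raw.mean()) / sd
        self.values = dict(zip(ALPHABET, self._h))

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(f"residue {residue!r} not in scale {self.name!r}") from None

    def as_array(self) -> np.ndarray:
        """Standardized values in :data:`ALPHABET` order (length 20)."""
        return self._h.copy()

    def encode(self, seq: str) -> np.ndarray:
        """Map a residue string to its standardized property profile."""
        idx = [ALPHABET.index(a) for a in seq]
        return self._h[idx]

    def __repr__(self) -> str:  # pragma: no cover
        return f"PropertyScale(name={self.name!r})"


def default_scales() -> dict[str, PropertyScale]:
    """The five built-in property scales keyed by name, in canonical order."""
    out: dict[str, PropertyScale] = {}
    for name in PROPERTY_NAMES:
        col = _FACTOR_OF[name]
        out[name] = PropertyScale(name, {a: _ATCHLEY[a][col] for a in ALPHABET})
    return out
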