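"""AAC and pseudo-amino-acid-composition (Pse-AAC) pair encoding.

Each HLA-protein/peptide pair is encoded as a 340-dimensional vector
``V = V_pro || V_pep``:

* ``V_pro`` (270) — protein amino-acid composition (20) plus, for each of
  the five property scales, lambda = 50 sequence-order correlation factors;
* ``V_pep`` (70) — peptide composition (20) plus lambda = 10 correlation
  factors per scale.

The per-property correlation factor at lag ``j`` is

    theta_j = (1 / (L - j)) * sum_{i=1..L-j} (H(R_{i+j}) - H(R_i))^2

with ``H`` the standardized property value of a residue, and the Pse-AAC
component for lag ``j`` is ``w * theta_j / (1 + w * sum_m theta_m)`` (the
AAC frequencies sum to one, so the classic normalizing denominator
``sum_k f_k + w * sum_m theta_m`` reduces to ``1 + w * sum theta``). Lags
at or beyond the sequence length carry no information and are set to zero,
which lets short peptides (8-10 residues) be encoded at lambda = 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import Dataset, HIGH
from .scales import ALPHABET, PROPERTY_NAMES, PropertyScale, default_scales

DEFAULT_LAMBDA_PROTEIN = 50
DEFAULT_LAMBDA_PEPTIDE = 10
DEFAULT_WEIGHT = 0.15

_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one feature: which entity, which category, which slot."""

    entity: str  # "protein" | "peptide"
    category: str  # "AAC" | one of the five property names
    position: int  # residue letter index (AAC) or lag, 1-based (Pse-AAC)

    @property
    def name(self) -> str:
        ent = "pro" if self.entity == "protein" else "pep"
        if self.category == "AAC":
            return f"{ent}_AAC_{ALPHABET[self.position - 1]}"
        return f"{ent}_{self.category}_{self.position}"


class FeatureCatalogue:
    """Ordered descriptors for every component of the pair feature vector.

    Block layout (``lambda_protein = 50``, ``lambda_peptide = 10`` by
    default): protein AAC 20, then 50 per property scale (CD, EC, MV,
    2nd_stru, polarity); peptide AAC 20, then 10 per scale — 270 + 70 = 340.
    """

    def __init__(
        self,
        lambda_protein: int = DEFAULT_LAMBDA_PROTEIN,
        lambda_peptide: int = DEFAULT_LAMBDA_PEPTIDE,
    ):
        self.lambda_protein = lambda_protein
        self.lambda_peptide = lambda_peptide
        descriptors: list[FeatureDescriptor] = []
        for entity, lam in (("protein", lambda_protein), ("peptide", lambda_peptide)):
            descriptors.extend(
                FeatureDescriptor(entity, "AAC", i + 1) for i in range(20)
            )
            for prop in PROPERTY_NAMES:
                descriptors.extend(
                    FeatureDescriptor(entity, prop, j + 1) for j in range(lam)
                )
        self.descriptors: tuple[FeatureDescriptor, ...] = tuple(descriptors)

    def __len__(self) -> int:
        return len(self.descriptors)

    def __getitem__(self, i: int) -> FeatureDescriptor:
        return self.descriptors[i]

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def block_sizes(self) -> dict[tuple[str, str], int]:
        """Total feature count per (entity, category) cell."""
        out: dict[tuple[str, str], int] = {}
        for d in self.descriptors:
            key = (d.entity, d.category)
            out[key] = out.get(key, 0) + 1
        return out


def compute_aac(seq: str) -> np.ndarray:
    """Amino-acid composition: residue occurrence frequencies.

    Returns a 20-vector in alphabetical single-letter order
    (``ACDEFGHIKLMNPQRSTVWY``); components sum to 1.
    """
    if not seq:
        raise ValueError("cannot compute composition of an empty sequence")
    counts = np.zeros(20)
    for a in seq:
        try:
            counts[_AA_INDEX[a]] += 1
        except KeyError:
            raise ValueError(f"non-standard residue {a!r}") from None
    return counts / len(seq)


def correlation_factor(seq: str, scale: PropertyScale, j: int) -> float:
    """Sequence-order correlation factor theta_j for one property scale.

    Mean squared difference of standardized property values between residues
    ``j`` positions apart. Zero when ``j >= len(seq)`` (no residue pair at
    that lag).
    """
    if j < 1:
        raise ValueError(f"lag must be >= 1, got {j}")
    L = len(seq)
    if j >= L:
        return 0.0
    h = scale.encode(seq)
    d = h[j:] - h[:-j]
    return float(np.mean(d * d))


def compute_pseaac(
    seq: str, scale: PropertyScale, lam: int, w: float = DEFAULT_WEIGHT
) -> np.ndarray:
    """Pse-AAC sequence-order components for one property scale.

    Component ``j`` (1-based) is ``w * theta_j / (1 + w * sum_m theta_m)``.
    Every component lies in [0, 1) and the block sums to strictly less
    than 1.
    """
    if lam < 1:
        raise ValueError(f"lambda must be >= 1, got {lam}")
    if w <= 0:
        raise ValueError(f"weight must be positive, got {w}")
    L = len(seq)
    h = scale.encode(seq)
    theta = np.zeros(lam)
    for j in range(1, min(lam, L - 1) + 1):
        d = h[j:] - h[:-j]
        theta[j - 1] = np.mean(d * d)
    return w * theta / (1.0 + w * theta.sum())


def _encode_entity(
    seq: str,
    lam: int,
    w: float,
    scales: dict[str, PropertyScale],
) -> np.ndarray:
    parts = [compute_aac(seq)]
    parts.extend(compute_pseaac(seq, scales[p], lam, w) for p in PROPERTY_NAMES)
    return np.concatenate(parts)


def encode_protein(
    seq: str,
    lam: int = DEFAULT_LAMBDA_PROTEIN,
    w: float = DEFAULT_WEIGHT,
    scales: dict[str, PropertyScale] | None = None,
) -> np.ndarray:
    """Encode an HLA protein: AAC (20) + 5 property blocks of ``lam`` each."""
    if len(seq) < 2:
        raise ValueError("protein sequence must have at least 2 residues")
    return _encode_entity(seq, lam, w, scales or default_scales())


def encode_peptide(
    seq: str,
    lam: int = DEFAULT_LAMBDA_PEPTIDE,
    w: float = DEFAULT_WEIGHT,
    scales: dict[str, PropertyScale] | None = None,
) -> np.ndarray:
    """Encode a peptide: AAC (20) + 5 property blocks of ``lam`` each."""
    if len(seq) < 2:
        raise ValueError("peptide sequence must have at least 2 residues")
    return _encode_entity(seq, lam, w, scales or default_scales())


def encode_pair(
    protein: str,
    peptide: str,
    lambda_protein: int = DEFAULT_LAMBDA_PROTEIN,
    lambda_peptide: int = DEFAULT_LAMBDA_PEPTIDE,
    w: float = DEFAULT_WEIGHT,
    scales: dict[str, PropertyScale] | None = None,
) -> np.ndarray:
    """Concatenated pair vector ``V = V_pro || V_pep`` (340 at defaults)."""
    scales = scales or default_scales()
    return np.concatenate(
        [
            encode_protein(protein, lambda_protein, w, scales),
            encode_peptide(peptide, lambda_peptide, w, scales),
        ]
    )


class PairEncoder(BaseEstimator, TransformerMixin):
    """Transform a :class:`~hlabind.io.Dataset` into the pair feature matrix.

    Parameters
    ----------
    lambda_protein, lambda_peptide : int
        Number of sequence-order correlation factors per property scale for
        the HLA protein (default 50) and the peptide (default 10).
    w : float
        Sequence-order weight balancing correlation factors against
        composition frequencies (default 0.15).
    scales : dict[str, PropertyScale] or None
        Property scales; ``None`` uses the five built-in factor scales.

    Attributes
    ----------
    catalogue_ : FeatureCatalogue
        Descriptor for every output column, set by :meth:`fit`.
    n_features_out_ : int
        Output dimensionality (340 at defaults).

    Examples
    --------
    >>> enc = PairEncoder().fit()
    >>> X = enc.transform(dataset)          # doctest: +SKIP
    >>> X.shape[1]                          # doctest: +SKIP
    340
    """

    def __init__(
        self,
        lambda_protein: int = DEFAULT_LAMBDA_PROTEIN,
        lambda_peptide: int = DEFAULT_LAMBDA_PEPTIDE,
        w: float = DEFAULT_WEIGHT,
        scales: dict[str, PropertyScale] | None = None,
    ):
        self.lambda_protein = lambda_protein
        self.lambda_peptide = lambda_peptide
        self.w = w
        self.scales = scales

    def fit(self, X: Dataset | None = None, y=None) -> "PairEncoder":
        """Build the feature catalogue; the encoding itself is stateless."""
        if self.lambda_protein < 1 or self.lambda_peptide < 1:
            raise ValueError("lambda parameters must be >= 1")
        if self.w <= 0:
            raise ValueError("w must be positive")
        self.catalogue_ = FeatureCatalogue(self.lambda_protein, self.lambda_peptide)
        self.n_features_out_ = len(self.catalogue_)
        self._scales = self.scales or default_scales()
        return self

    def transform(self, dataset: Dataset) -> np.ndarray:
        """Encode every interaction record; rows follow record order."""
        if not hasattr(self, "catalogue_"):
            raise RuntimeError("PairEncoder must be fitted before transform")
        pro_cache: dict[str, np.ndarray] = {}
        pep_cache: dict[str, np.ndarray] = {}
        rows = np.empty((len(dataset.records), self.n_features_out_))
        for i, rec in enumerate(dataset.records):
            vp = pro_cache.get(rec.allele_id)
            if vp is None:
                vp = encode_protein(
                    dataset.alleles[rec.allele_id].residues,
                    self.lambda_protein, self.w, self._scales,
                )
                pro_cache[rec.allele_id] = vp
            vq = pep_cache.get(rec.peptide)
            if vq is None:
                vq = encode_peptide(rec.peptide, self.lambda_peptide, self.w, self._scales)
                pep_cache[rec.peptide] = vq
            rows[i, : vp.size] = vp
            rows[i, vp.size :] = vq
        return rows

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.catalogue_.names, dtype=object)


def encode_dataset(
    dataset: Dataset, encoder: PairEncoder | None = None
) -> tuple[np.ndarray, np.ndarray, FeatureCatalogue]:
    """Encode a dataset; returns (X, y, catalogue) with y = 1 for high affinity."""
    encoder = (encoder or PairEncoder()).fit()
    X = encoder.transform(dataset)
    y = np.array([1 if r.label == HIGH else 0 for r in dataset.records])
    return X, y, encoder.catalogue_


def write_feature_matrix(path, X: np.ndarray, y: np.ndarray, catalogue: FeatureCatalogue) -> None:
    """Write the feature matrix as TSV: catalogue-named columns plus ``label``."""
    import pandas as pd

    df = pd.DataFrame(X, columns=catalogue.names)
    df["label"] = np.where(np.asarray(y) == 1, "high", "low")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
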