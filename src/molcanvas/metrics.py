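"""Distribution-learning metrics for generated molecule sets.

The MOSES-style suite: validity, uniqueness@k, novelty, internal
diversity (IntDiv), similarity to nearest neighbour (SNN), a Frechet
distance over a pluggable featurizer, BRICS-fragment and Bemis-Murcko
scaffold cosine similarities, and property distributions.

Conventions:

* IntDiv_p(G) = 1 - (|G|^-2 * sum over all ordered pairs, self-pairs
  included, of T(m1, m2)^p)^(1/p) with Morgan-fingerprint Tanimoto T;
* SNN(G, R) = mean over G of the maximum Tanimoto against R;
* Frechet(G, R) = ||mu_G - mu_R||^2 + Tr(S_G + S_R - 2 (S_G S_R)^{1/2});
  the default featurizer is a fixed vector of cheap RDKit descriptors,
  so values are not comparable to ChemNet-based FCD numbers — reports
  carry the featurizer name;
* Frag/Scaf = cosine similarity between substructure frequency vectors;
* validity/uniqueness/novelty operate on canonical forms; unique@k is
  computed over the first k valid samples (the MOSES convention).

Strings in other representations (SELFIES, DeepSMILES) are decoded to
SMILES first via ``decode_molecules``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import chem


@dataclass
class MoleculeSet:
    """A named list of molecule strings (generated / reference / training)."""
    molecules: list[str]
    role: str = "generated"

    def __post_init__(self):
        if any(not m for m in self.molecules):
            raise ValueError("molecule strings must be non-empty")

    def __len__(self) -> int:
        return len(self.molecules)


def _strings(G) -> list[str]:
    return list(G.molecules) if isinstance(G, MoleculeSet) else list(G)


def decode_molecules(strings: Sequence[str], representation: str = "SMILES"
                     ) -> list[str]:
    """Decode generated strings to SMILES ('' marks a failed decode)."""
    rep = representation.upper()
    if rep == "SMILES":
        return list(strings)
    if rep == "SELFIES":
        from .selfies_codec import decode
        return [decode(s) for s in strings]
    if rep == "DEEPSMILES":
        from .deepsmiles_codec import DeepSmilesError, from_deepsmiles
        out = []
        for s in strings:
            try:
                out.append(from_deepsmiles(s))
            except DeepSmilesError:
                out.append("")
        return out
    raise ValueError(f"unknown representation {representation!r}")


# ---------------------------------------------------------------------------
# Validity / uniqueness / novelty
# ---------------------------------------------------------------------------

def validity(G, representation: str = "SMILES") -> float:
    """Fraction of strings parsing to a valence-legal molecule."""
    mols = decode_molecules(_strings(G), representation)
    if not mols:
        raise ValueError("validity of an empty set is undefined")
    return float(np.mean([chem.is_valid(m) for m in mols]))


def _canonical_valid(strings: Sequence[str], representation: str
                     ) -> list[str]:
    out = []
    for m in decode_molecules(strings, representation):
        c = chem.canonical_smiles(m) if m else None
        if c is not None:
            out.append(c)
    return out


def uniqueness_at_k(G, k: int, representation: str = "SMILES") -> float:
    """Distinct canonical forms among the first k valid samples, over k."""
    strings = _strings(G)
    if k > len(strings):
        raise ValueError(f"k={k} exceeds |G|={len(strings)}")
    valid = _canonical_valid(strings, representation)[:k]
    return len(set(valid)) / k


def novelty(G, training, representation: str = "SMILES") -> float:
    """Fraction of valid generated canonicals absent from the training set."""
    train = _strings(training)
    if not train:
        raise ValueError("empty training set")
    gen = _canonical_valid(_strings(G), representation)
    if not gen:
        raise ValueError("no valid generated molecules")
    ref = {chem.canonical_smiles(m) for m in train}
    ref.discard(None)
    return float(np.mean([g not in ref for g in gen]))


# ---------------------------------------------------------------------------
# Fingerprint metrics
# ---------------------------------------------------------------------------

@dataclass
class FingerprintParams:
    radius: int = 2
    n_bits: int = 1024


def _fingerprints(strings: Sequence[str], params: FingerprintParams
                  ) -> np.ndarray:
    fps = [chem.morgan_fingerprint(m, params.radius, params.n_bits)
           for m in strings]
    fps = [f for f in fps if f is not None]
    if not fps:
        raise ValueError("no valid molecules to fingerprint")
    return np.array(fps, dtype=bool)


def _pairwise_tanimoto(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """(len(A), len(B)) Tanimoto matrix over boolean fingerprint rows."""
    A = A.astype(np.float64)
    B = B.astype(np.float64)
    inter = A @ B.T
    union = A.sum(1)[:, None] + B.sum(1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(union > 0, inter / union, 1.0)
    return T


def int_div(G, p: int = 1, params: FingerprintParams | None = None,
            fingerprints: np.ndarray | None = None) -> float:
    """Internal diversity of a set (1 minus the power-mean pairwise
    Tanimoto over all ordered pairs, self-pairs included)."""
    if fingerprints is None:
        strings = _strings(G)
        if not strings:
            raise ValueError("empty set")
        fingerprints = _fingerprints(strings, params or FingerprintParams())
    T = _pairwise_tanimoto(fingerprints, fingerprints)
    return float(1.0 - (np.mean(T ** p)) ** (1.0 / p))


def snn(G, R, params: FingerprintParams | None = None,
        fingerprints_g: np.ndarray | None = None,
        fingerprints_r: np.ndarray | None = None) -> float:
    """Mean nearest-neighbour Tanimoto of G against the reference R."""
    params = params or FingerprintParams()
    if fingerprints_g is None:
        fingerprints_g = _fingerprints(_strings(G), params)
    if fingerprints_r is None:
        R = _strings(R)
        if not R:
            raise ValueError("empty reference set")
        fingerprints_r = _fingerprints(R, params)
    T = _pairwise_tanimoto(fingerprints_g, fingerprints_r)
    return float(np.mean(T.max(axis=1)))


# ---------------------------------------------------------------------------
# Frechet distance
# ---------------------------------------------------------------------------

@dataclass
class FrechetStats:
    mu: np.ndarray
    sigma: np.ndarray
    n: int
    n_failed: int = 0


def frechet_stats(strings: Sequence[str],
                  featurizer: Callable[[str], np.ndarray | None] | None = None
                  ) -> FrechetStats:
    """Gaussian summary (mu, Sigma) of featurized molecules.

    Molecules the featurizer rejects are skipped and counted.
    """
    featurizer = featurizer or chem.descriptor_features
    feats = []
    failed = 0
    for m in strings:
        f = featurizer(m)
        if f is None:
            failed += 1
        else:
            feats.append(np.atleast_1d(np.asarray(f, dtype=float)))
    if not feats:
        raise ValueError("featurizer rejected every molecule")
    X = np.array(feats)
    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False) if len(X) > 1 else np.zeros(
        (X.shape[1], X.shape[1]))
    sigma = np.atleast_2d(sigma)
    return FrechetStats(mu=mu, sigma=sigma, n=len(X), n_failed=failed)


def _psd_sqrt(S: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition, eigenvalues
    clipped at zero."""
    S = (S + S.T) / 2.0
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    return (V * np.sqrt(w)) @ V.T


def frechet_from_stats(a: FrechetStats, b: FrechetStats) -> float:
    """||mu_a - mu_b||^2 + Tr(Sa + Sb - 2 (Sa Sb)^{1/2}).

    Tr((Sa Sb)^{1/2}) is evaluated as Tr((Sa^{1/2} Sb Sa^{1/2})^{1/2}),
    which is symmetric PSD and equal in trace.
    """
    diff = a.mu - b.mu
    ra = _psd_sqrt(a.sigma)
    inner = _psd_sqrt(ra @ b.sigma @ ra)
    val = float(diff @ diff + np.trace(a.sigma) + np.trace(b.sigma)
                - 2.0 * np.trace(inner))
    return max(val, 0.0)


def frechet_distance(G, R,
                     featurizer: Callable[[str], np.ndarray | None] | None = None
                     ) -> float:
    """Frechet distance between Gaussian feature summaries of two sets."""
    return frechet_from_stats(frechet_stats(_strings(G), featurizer),
                              frechet_stats(_strings(R), featurizer))


# ---------------------------------------------------------------------------
# Substructure frequency metrics
# ---------------------------------------------------------------------------

def cosine_counts(cg: dict, cr: dict) -> float:
    """Cosine similarity between two sparse count vectors (0 if a side
    is empty)."""
    keys = set(cg) | set(cr)
    if not keys:
        return 0.0
    g = np.array([cg.get(k, 0) for k in keys], dtype=float)
    r = np.array([cr.get(k, 0) for k in keys], dtype=float)
    ng, nr = np.linalg.norm(g), np.linalg.norm(r)
    if ng == 0 or nr == 0:
        return 0.0
    return float(g @ r / (ng * nr))


def _substructure_counts(strings: Sequence[str],
                         extractor: Callable[[str], list[str]]) -> Counter:
    counts: Counter = Counter()
    for m in strings:
        counts.update(extractor(m))
    return counts


def frag_similarity(G, R, counts_g: dict | None = None,
                    counts_r: dict | None = None) -> float:
    """Cosine similarity of BRICS-fragment frequency vectors."""
    if counts_g is None:
        counts_g = _substructure_counts(_strings(G), chem.brics_fragments)
    if counts_r is None:
        counts_r = _substructure_counts(_strings(R), chem.brics_fragments)
    return cosine_counts(counts_g, counts_r)


def _scaffolds(m: str) -> list[str]:
    s = chem.murcko_scaffold(m)
    return [s] if s else []


def scaf_similarity(G, R, counts_g: dict | None = None,
                    counts_r: dict | None = None) -> float:
    """Cosine similarity of Bemis-Murcko scaffold frequency vectors."""
    if counts_g is None:
        counts_g = _substructure_counts(_strings(G), _scaffolds)
    if counts_r is None:
        counts_r = _substructure_counts(_strings(R), _scaffolds)
    return cosine_counts(counts_g, counts_r)


# ---------------------------------------------------------------------------
# Property distributions and reports
# ---------------------------------------------------------------------------

@dataclass
class PropertySummary:
    property: str
    values: np.ndarray
    n: int
    n_excluded: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    def histogram(self, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.values, bins=bins)


def property_distribution(G, prop: str,
                          property_fn: Callable[[str], float | None] | None = None
                          ) -> PropertySummary:
    """Per-molecule property values plus a summary.

    Molecules the adapter cannot compute are excluded and counted, as the
    benchmark convention requires.  ``property_fn`` overrides the adapter
    (e.g. a heavy-atom-count proxy).
    """
    if property_fn is None:
        if prop not in chem.PROPERTIES:
            raise ValueError(f"unknown property {prop!r}; "
                             f"expected one of {chem.PROPERTIES}")
        property_fn = lambda m: chem.compute_property(m, prop)  # noqa: E731
    vals = []
    excluded = 0
    for m in _strings(G):
        v = property_fn(m)
        if v is None:
            excluded += 1
        else:
            vals.append(v)
    if not vals:
        raise ValueError(f"property {prop!r} computable for no molecule")
    return PropertySummary(property=prop, values=np.array(vals),
                           n=len(vals), n_excluded=excluded)


@dataclass
class MetricReport:
    """Named metric values with the parameterization and set sizes used."""
    metrics: dict[str, float] = field(default_factory=dict)
    parameters: dict[str, object] = field(default_factory=dict)
    n_generated: int = 0
    n_reference: int = 0

    def to_dict(self) -> dict:
        return {name: {"value": v, "parameters": self.parameters,
                       "n": self.n_generated}
                for name, v in self.metrics.items()}


def evaluate(G, R=None, training=None, representation: str = "SMILES",
             k_unique: int | None = None,
             params: FingerprintParams | None = None,
             featurizer=None) -> MetricReport:
    """Standard metric sweep for a generated set against references."""
    strings = _strings(G)
    params = params or FingerprintParams()
    report = MetricReport(
        parameters={"radius": params.radius, "n_bits": params.n_bits,
                    "representation": representation,
                    "featurizer": "rdkit_descriptors" if featurizer is None
                    else getattr(featurizer, "__name__", "custom")},
        n_generated=len(strings))
    m = report.metrics
    m["validity"] = validity(strings, representation)
    k = k_unique or min(1000, len(strings))
    m[f"unique@{k}"] = uniqueness_at_k(strings, k, representation)
    valid = _canonical_valid(strings, representation)
    if valid:
        fps = _fingerprints(valid, params)
        m["int_div"] = int_div(None, p=1, fingerprints=fps)
        m["int_div2"] = int_div(None, p=2, fingerprints=fps)
        if R is not None:
            ref = _strings(R)
            report.n_reference = len(ref)
            m["snn"] = snn(valid, ref, params)
            m["frag"] = frag_similarity(valid, ref)
            m["scaf"] = scaf_similarity(valid, ref)
            m["frechet"] = frechet_distance(valid, ref, featurizer)
        if training is not None:
            m["novelty"] = novelty(strings, training, representation)
    return report
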