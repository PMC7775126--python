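"""Mutational spectra, trinucleotide context matrices and signature refitting.

Substitutions are collapsed onto the pyrimidine strand, giving the six
classes C>A, C>G, C>T, T>A, T>C, T>G; with the flanking bases this yields
the standard 96 trinucleotide-context substitution types (class-major order,
contexts lexicographic within class). Per-sample exposures to a signature
catalog are refit by non-negative least squares (NNLS) and renormalized to
sum to one; the cosine similarity between the observed and reconstructed
96-vector is reported so catalog-fit quality is always checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import PCA

from .io import MutationRecord

__all__ = [
    "SUBSTITUTION_CLASSES",
    "CONTEXTS_96",
    "SpectrumVector",
    "SignatureCatalog",
    "ExposureProfile",
    "collapse_substitution",
    "spectrum",
    "context_matrix",
    "fit_exposures",
    "spectrum_pca",
    "cosine_similarity",
]

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _build_contexts() -> tuple[tuple[str, str], ...]:
    out = []
    for cls in SUBSTITUTION_CLASSES:
        ref = cls[0]
        for five in "ACGT":
            for three in "ACGT":
                out.append((cls, five + ref + three))
    return tuple(out)


#: The 96 (class, trinucleotide) context types in canonical order.
CONTEXTS_96 = _build_contexts()

#: "T[C>A]A"-style labels, the common interchange format.
CONTEXT_LABELS = tuple(f"{ctx[0]}[{cls}]{ctx[2]}" for cls, ctx in CONTEXTS_96)

_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def collapse_substitution(
    ref: str, alt: str, context3: str | None = None
) -> tuple[str, str | None]:
    """Collapse a substitution onto the pyrimidine strand.

    Purine-reference changes are reverse-complemented (ref, alt and
    context); returns the six-class label and the collapsed trinucleotide
    context (``None`` if no context was given).
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT base in substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref equals alt")
    ctx = context3.upper() if context3 else None
    if ctx is not None:
        if len(ctx) != 3 or any(b not in _COMPLEMENT for b in ctx):
            raise ValueError(f"malformed trinucleotide context {context3!r}")
        if ctx[1] != ref:
            raise ValueError(f"context {context3!r} does not centre on ref {ref!r}")
    if ref in "AG":  # purine reference: flip strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        if ctx is not None:
            ctx = _revcomp(ctx)
    return f"{ref}>{alt}", ctx


@dataclass
class SpectrumVector:
    """Proportions of the six substitution classes for one sample."""

    proportions: pd.Series  # indexed by SUBSTITUTION_CLASSES
    n_snv: int
    n_indel_ignored: int = 0

    @property
    def empty(self) -> bool:
        return self.n_snv == 0

    def __post_init__(self) -> None:
        p = self.proportions
        if list(p.index) != list(SUBSTITUTION_CLASSES):
            raise ValueError("proportions must be indexed by the 6 classes")
        if self.n_snv > 0:
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("proportions must be a distribution")


def spectrum(records: Iterable[MutationRecord]) -> SpectrumVector:
    """Six-class substitution spectrum of one sample's records.

    Indels are ignored (their number is reported on the result).
    """
    counts = dict.fromkeys(SUBSTITUTION_CLASSES, 0)
    n_indel = 0
    for r in records:
        if r.variant_type != "SNP":
            n_indel += 1
            continue
        cls, _ = collapse_substitution(r.ref, r.alt, None)
        counts[cls] += 1
    n = sum(counts.values())
    if n > 0:
        props = pd.Series({k: v / n for k, v in counts.items()})
    else:
        props = pd.Series(dict.fromkeys(SUBSTITUTION_CLASSES, 0.0))
    props = props.reindex(list(SUBSTITUTION_CLASSES))
    return SpectrumVector(proportions=props, n_snv=n, n_indel_ignored=n_indel)


def context_matrix(
    records: Iterable[MutationRecord], samples: Sequence[str] | None = None
) -> pd.DataFrame:
    """Samples x 96 integer count matrix of trinucleotide context types.

    Only SNVs carrying a context participate; columns follow
    :data:`CONTEXT_LABELS`.
    """
    per_sample: dict[str, np.ndarray] = {}
    for r in records:
        if r.variant_type != "SNP" or not r.context3:
            continue
        cls, ctx = collapse_substitution(r.ref, r.alt, r.context3)
        row = per_sample.setdefault(r.sample_id, np.zeros(96, dtype=int))
        row[_CONTEXT_INDEX[(cls, ctx)]] += 1
    if samples is None:
        samples = list(per_sample)
    data = np.vstack(
        [per_sample.get(s, np.zeros(96, dtype=int)) for s in samples]
    ) if samples else np.zeros((0, 96), dtype=int)
    return pd.DataFrame(
        data, index=pd.Index(samples, name="sample_id"), columns=list(CONTEXT_LABELS)
    )


@dataclass
class SignatureCatalog:
    """96 x K matrix of column-stochastic signature profiles."""

    profiles: pd.DataFrame  # index = CONTEXT_LABELS, columns = signature names

    def __post_init__(self) -> None:
        p = self.profiles
        if list(p.index) != list(CONTEXT_LABELS):
            raise ValueError("catalog rows must follow the canonical 96-context order")
        if (p.values < 0).any():
            raise ValueError("negative signature entries")
        sums = p.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("signature columns must sum to 1")

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)


def read_catalog(path) -> SignatureCatalog:
    """Read a signature catalog in the COSMIC-v2 text layout.

    Expects ``Substitution Type`` and ``Trinucleotide`` columns (any order)
    followed by one column per signature; rows may be in any order.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        sub_col = cols["substitution type"]
        tri_col = cols["trinucleotide"]
    except KeyError as e:
        raise ValueError(f"{path}: missing COSMIC-v2 header column {e}") from e
    labels = [
        f"{tri[0]}[{sub}]{tri[2]}"
        for sub, tri in zip(df[sub_col], df[tri_col])
    ]
    sig_cols = [
        c for c in df.columns
        if c not in (sub_col, tri_col) and not c.strip().lower().startswith("somatic mutation")
    ]
    prof = df[sig_cols].copy()
    prof.index = labels
    prof = prof.reindex(list(CONTEXT_LABELS))
    if prof.isna().any().any():
        raise ValueError(f"{path}: catalog does not cover all 96 context types")
    prof = prof / prof.sum(axis=0)
    return SignatureCatalog(profiles=prof)


def write_catalog(catalog: SignatureCatalog, path) -> None:
    """Write a catalog in the COSMIC-v2 text layout."""
    rows = []
    for (cls, tri), (_, prof) in zip(CONTEXTS_96, catalog.profiles.iterrows()):
        row = {"Substitution Type": cls, "Trinucleotide": tri,
               "Somatic Mutation Type": f"{tri[0]}[{cls}]{tri[2]}"}
        row.update(prof.to_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ExposureProfile:
    """Refitted non-negative signature weights for one sample."""

    weights: pd.Series  # indexed by signature names; sums to 1
    cosine: float  # observed vs reconstructed 96-vector

    def __post_init__(self) -> None:
        if (self.weights < 0).any():
            raise ValueError("negative exposure weight")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("exposure weights must sum to 1")
        if not (0.0 <= self.cosine <= 1.0 + 1e-12):
            raise ValueError(f"cosine out of [0, 1]: {self.cosine}")


def cosine_similarity(u, v) -> float:
    """Cosine similarity of two vectors; errors on a zero vector."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def fit_exposures(context_counts, catalog: SignatureCatalog) -> ExposureProfile:
    """NNLS refit of one sample's 96-context counts against a catalog.

    The counts are normalized to a distribution, so exposures are invariant
    to scaling the input by a positive constant.
    """
    x = np.asarray(context_counts, dtype=float)
    if x.shape != (96,):
        raise ValueError(f"expected a 96-vector, got shape {x.shape}")
    if (x < 0).any():
        raise ValueError("negative context counts")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero context counts: no exposures to fit")
    target = x / total
    A = catalog.profiles.values
    w, _ = nnls(A, target)
    recon = A @ w
    cos = min(1.0, cosine_similarity(target, recon)) if recon.any() else 0.0
    if w.sum() == 0:  # pathological: catalog orthogonal to data
        weights = pd.Series(np.full(A.shape[1], 1.0 / A.shape[1]), index=catalog.names)
    else:
        weights = pd.Series(w / w.sum(), index=catalog.names)
    return ExposureProfile(weights=weights, cosine=cos)


def fit_cohort_exposures(
    contexts: pd.DataFrame, catalog: SignatureCatalog
) -> pd.DataFrame:
    """Refit every row of a samples x 96 matrix; returns samples x (K+1)
    with a trailing ``cosine`` column. All-zero rows are skipped."""
    rows = {}
    for s, row in contexts.iterrows():
        if row.sum() == 0:
            continue
        prof = fit_exposures(row.values, catalog)
        rows[s] = pd.concat([prof.weights, pd.Series({"cosine": prof.cosine})])
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    return out


def spectrum_pca(
    spectra: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of per-sample spectrum proportion vectors.

    ``spectra`` is samples x classes (6 or 96 columns). Returns per-sample
    coordinates and the explained-variance fractions.
    """
    X = spectra.values.astype(float)
    if X.shape[0] < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} samples for {n_components} components"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    out = pd.DataFrame(
        coords, index=spectra.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return out, pca.explained_variance_ratio_
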