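"""Bundled signature catalog (synthetic).

The package ships a small three-column catalog in the COSMIC-v2 text layout
for simulation and demos. The profiles are SYNTHETIC stand-ins built here,
not the published COSMIC matrices: they reproduce the qualitative structure
of a CpG-deamination clock process ("sig1-like"), a UV dipyrimidine C>T
process ("sig7-like") and a broad C>T/T>C process ("sig30-like"), which is
what the downstream refitting machinery needs to be exercised and tested.
Users analysing real cohorts should point ``--catalog`` at a full published
catalog file in the same layout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spectrum import CONTEXT_LABELS, CONTEXTS_96, SignatureCatalog

__all__ = ["synthetic_catalog", "default_catalog"]

_JITTER_SEED = 20201231  # fixed: the catalog is a constant of the package


def _profile(class_mass: dict[str, float], concentrate) -> np.ndarray:
    """Build one 96-profile: per-class mass split over contexts, optionally
    concentrated on contexts selected by ``concentrate(cls, tri)``."""
    rng = np.random.default_rng(_JITTER_SEED)
    p = np.zeros(96)
    for ci, (cls, tri) in enumerate(CONTEXTS_96):
        mass = class_mass.get(cls, 0.0)
        if mass == 0.0:
            continue
        hot = concentrate(cls, tri) if concentrate else False
        p[ci] = (8.0 if hot else 1.0) * (0.7 + 0.6 * rng.random())
        p[ci] *= mass
    # renormalize each class block to its intended mass, then the whole
    for cls, mass in class_mass.items():
        idx = [i for i, (c, _) in enumerate(CONTEXTS_96) if c == cls]
        block = p[idx]
        if block.sum() > 0:
            p[idx] = block / block.sum() * mass
    return p / p.sum()


def synthetic_catalog() -> SignatureCatalog:
    """Deterministic synthetic 96x3 catalog (sig1/7/30-like columns)."""
    sig1 = _profile(
        {"C>T": 0.75, "T>C": 0.15, "C>A": 0.04, "C>G": 0.02, "T>A": 0.02, "T>G": 0.02},
        concentrate=lambda cls, tri: cls == "C>T" and tri[2] == "G",  # NpCpG
    )
    sig7 = _profile(
        {"C>T": 0.90, "C>A": 0.03, "T>C": 0.04, "C>G": 0.01, "T>A": 0.01, "T>G": 0.01},
        concentrate=lambda cls, tri: cls == "C>T" and tri[0] in "CT",  # dipyrimidine
    )
    # peaks kept disjoint from the other two columns (non-CpG, purine-5' C>T
    # plus T>C) so the three profiles are mutually identifiable
    sig30 = _profile(
        {"C>T": 0.45, "T>C": 0.25, "C>A": 0.12, "T>A": 0.06, "C>G": 0.06, "T>G": 0.06},
        concentrate=lambda cls, tri: (cls == "T>C") or (
            cls == "C>T" and tri[0] in "AG" and tri[2] != "G"
        ),
    )
    prof = pd.DataFrame(
        {"Signature_1": sig1, "Signature_7": sig7, "Signature_30": sig30},
        index=list(CONTEXT_LABELS),
    )
    return SignatureCatalog(profiles=prof)


def default_catalog() -> SignatureCatalog:
    """The catalog used by the simulator and as the CLI fallback."""
    return synthetic_catalog()
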