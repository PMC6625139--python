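"""Bundled signature probability matrix.

The package ships a SYNTHETIC stand-in for the classic 30-signature x 96
context probability table (``data/signature_matrix_synthetic.tsv``). The
real published table is not redistributed here; the synthetic one is
generated deterministically by :func:`synthetic_signature_matrix` and keeps
the qualitative structure that the analysis relies on:

* Signature 1  — C>T concentrated at NpCpG contexts (5-methylcytosine
  deamination).
* Signature 6 / Signature 15 — distinct C>T-rich profiles standing in for
  the two defective-MMR signatures.
* Signature 7  — C>T at dipyrimidine (5'-T) contexts (ultraviolet damage).
* Signature 4 / Signature 29 — C>A-rich tobacco-style profiles.
* The remaining signatures are sparse random profiles, mutually distinct.

Every row sums to 1 and follows the catalog's context order, so mixtures
simulated from this matrix exercise exactly the same code paths as the
published table would.
"""

from __future__ import annotations

from importlib import resources as _ilr

import numpy as np

from .catalog import BASES, CONTEXT_LABELS, label_to_index
from .refit import SignatureMatrix

SIGNATURE_IDS = [f"Signature {i}" for i in range(1, 31)]
_MATRIX_SEED = 96301  # fixed: the shipped TSV is this generator's output
_DATA_FILE = "signature_matrix_synthetic.tsv"

#: Bins emphasised by the thematically structured signatures.
_THEMES = {
    "Signature 1": [f"{f}[C>T]G" for f in BASES],
    "Signature 4": [f"{f}[C>A]{t}" for f in "CT" for t in BASES],
    "Signature 6": [f"G[C>T]{t}" for t in "ACT"] + ["C[C>T]C", "C[C>T]T", "A[C>T]A"],
    "Signature 7": [f"T[C>T]{t}" for t in BASES] + ["C[C>T]C", "C[C>T]A"],
    "Signature 15": [f"{f}[C>T]{t}" for f in "AG" for t in "G"]
    + ["T[C>G]T", "A[C>G]A", "G[C>G]G", "T[T>C]T"],
    "Signature 29": [f"{f}[C>A]A" for f in BASES] + ["T[C>A]T"],
}


def synthetic_signature_matrix(seed: int = _MATRIX_SEED) -> SignatureMatrix:
    """Deterministically generate the synthetic 30 x 96 signature matrix.

    Each signature is a Dirichlet draw with a small baseline concentration
    everywhere and strong concentration on ~6-16 "active" bins — thematic
    bins for the signatures named above, random disjoint-ish sets for the
    rest — which makes the signatures well separated (low pairwise cosine)
    and mixtures of them recoverable.
    """
    rng = np.random.default_rng(seed)
    probs = np.zeros((30, 96))
    for i, sig in enumerate(SIGNATURE_IDS):
        alpha = np.full(96, 0.04)
        if sig in _THEMES:
            active = [label_to_index(lab) for lab in _THEMES[sig]]
        else:
            active = rng.choice(96, size=10, replace=False)
        alpha[np.asarray(active)] = 3.0
        probs[i] = rng.dirichlet(alpha)
    return SignatureMatrix(ids=SIGNATURE_IDS, probs=probs)


def load_signature_matrix(path=None) -> SignatureMatrix:
    """Load a signature matrix TSV; defaults to the packaged synthetic one."""
    if path is not None:
        return SignatureMatrix.from_tsv(path)
    with _ilr.as_file(_ilr.files("sebsig").joinpath("data", _DATA_FILE)) as p:
        return SignatureMatrix.from_tsv(p)


def _write_packaged_matrix() -> None:  # pragma: no cover - build helper
    import pathlib

    out = pathlib.Path(__file__).parent / "data" / _DATA_FILE
    synthetic_signature_matrix().to_tsv(out)


if __name__ == "__main__":  # pragma: no cover
    _write_packaged_matrix()
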