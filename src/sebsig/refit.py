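"""Signature refitting: decompose a 96-bin catalog over predefined signatures.

The model assumes a sample's mutation spectrum is a convex combination of a
fixed set of signature probability vectors. Exposures are estimated by
greedy forward selection: starting from the empty model, each iteration
tries every candidate signature, finds the convex mixing weight that
maximizes cosine similarity between the observed spectrum and the blended
reconstruction (bounded golden-section search on [0, 1]), and accepts the
best candidate only if it improves similarity by more than a tolerance.
After convergence, exposures below a floor are zeroed and the remainder is
renormalized to sum to one. This mirrors the refitting strategy popularised
by deconstructSigs; a sum-of-squares objective is available as an
alternative through :class:`RefitConfig`.

Exposures are mutation-fraction contributions (the catalog is normalized to
frequencies before fitting), reported as percentages in summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import CONTEXT_LABELS, TrinucleotideCatalog

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def cosine_similarity(a, b) -> float:
    """cos(a, b) = a.b / (|a||b|) for non-negative, non-zero vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity of a zero vector is undefined")
    return float(a @ b / (na * nb))


@dataclass
class SignatureMatrix:
    """Named set of signature probability vectors over the 96 contexts.

    ``probs`` rows each sum to 1 and follow the catalog's context order.
    """

    ids: list[str]
    probs: np.ndarray

    def __post_init__(self):
        self.ids = list(self.ids)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.ids), 96):
            raise ValueError(
                f"expected ({len(self.ids)}, 96) matrix, got {self.probs.shape}"
            )
        if (self.probs < 0).any():
            raise ValueError("negative signature probability")
        bad = np.abs(self.probs.sum(axis=1) - 1.0) > 1e-6
        if bad.any():
            raise ValueError(f"signature rows do not sum to 1: {np.flatnonzero(bad)}")

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, sig_id: str) -> int:
        try:
            return self.ids.index(sig_id)
        except ValueError:
            raise KeyError(f"unknown signature id {sig_id!r}") from None

    def row(self, sig_id: str) -> np.ndarray:
        return self.probs[self.index_of(sig_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=self.ids, columns=CONTEXT_LABELS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SignatureMatrix":
        """Build from a (signatures x 96 contexts) or transposed frame."""
        if set(CONTEXT_LABELS).issubset(df.index):
            df = df.loc[CONTEXT_LABELS].T
        elif set(CONTEXT_LABELS).issubset(df.columns):
            df = df[CONTEXT_LABELS]
        else:
            raise ValueError("dataframe does not carry the 96 context labels")
        return cls(ids=list(df.index), probs=df.to_numpy())

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        """Read the TSV dialect: context-labelled rows, one column per id."""
        return cls.from_dataframe(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.to_dataframe().T.rename_axis("context").to_csv(
            path, sep="\t", float_format="%.8g"
        )


@dataclass
class RefitConfig:
    """Tuning knobs for the greedy refit.

    weight_floor : exposures below this fraction are discarded after
        convergence and the rest renormalized (0.06 follows the common
        refitting practice of ignoring sub-6% contributions).
    improvement_tol : minimum objective gain for accepting an iteration.
    max_iterations : hard cap on accepted iterations.
    objective : "cosine" (default) or "sse" (negative sum of squared
        residuals of the frequency reconstruction).
    """

    weight_floor: float = 0.06
    improvement_tol: float = 1e-4
    max_iterations: int = 50
    objective: str = "cosine"

    def __post_init__(self):
        if not 0.0 <= self.weight_floor < 0.5:
            raise ValueError("weight_floor must be in [0, 0.5)")
        if self.improvement_tol <= 0:
            raise ValueError("improvement_tol must be positive")
        if self.objective not in ("cosine", "sse"):
            raise ValueError(f"unknown objective {self.objective!r}")


def _golden_max(f, tol: float = 1e-4) -> tuple[float, float]:
    """Maximize a unimodal f on [0, 1]; returns (argmax, max)."""
    a, b = 0.0, 1.0
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    x = (a + b) / 2.0
    return x, f(x)


class SignatureRefit:
    """Model object tying one catalog to one signature set.

    Parameters
    ----------
    catalog : :class:`~sebsig.catalog.TrinucleotideCatalog` or a length-96
        count/frequency vector. Must not be all zero.
    signatures : :class:`SignatureMatrix`.
    config : :class:`RefitConfig`, optional.

    Examples
    --------
    >>> res = SignatureRefit(catalog, signatures).fit()
    >>> res.exposures.head()
    >>> res.combined(["Signature 6", "Signature 15"])
    """

    def __init__(self, catalog, signatures: SignatureMatrix, config: RefitConfig | None = None):
        if isinstance(catalog, TrinucleotideCatalog):
            vec = catalog.counts.astype(float)
        else:
            vec = np.asarray(catalog, dtype=float)
        if vec.shape != (96,):
            raise ValueError("catalog must have 96 bins")
        if (vec < 0).any():
            raise ValueError("negative catalog entry")
        if vec.sum() <= 0:
            raise ValueError("refusing to refit an all-zero catalog")
        self.target = vec / vec.sum()
        self.signatures = signatures
        self.config = config or RefitConfig()

    def _score(self, recon: np.ndarray) -> float:
        if self.config.objective == "cosine":
            return cosine_similarity(self.target, recon)
        return -float(((self.target - recon) ** 2).sum())

    def fit(self) -> "SignatureRefitResults":
        cfg = self.config
        sigs = self.signatures.probs
        n = len(self.signatures)
        weights = np.zeros(n)
        recon = np.zeros(96)
        trajectory: list[float] = []
        best_score = -np.inf
        for _ in range(cfg.max_iterations):
            cand_best = None  # (score, sig index, alpha)
            for j in range(n):
                row = sigs[j]
                if not weights.any():
                    # empty model: any alpha>0 gives the same direction
                    alpha, score = 1.0, self._score(row)
                else:
                    alpha, score = _golden_max(
                        lambda a, row=row: self._score((1 - a) * recon + a * row)
                    )
                if cand_best is None or score > cand_best[0]:
                    cand_best = (score, j, alpha)
            score, j, alpha = cand_best
            if trajectory and score - best_score <= cfg.improvement_tol:
                break
            weights = (1 - alpha) * weights
            weights[j] += alpha
            recon = weights @ sigs
            best_score = self._score(recon)
            trajectory.append(best_score)
        weights[weights < cfg.weight_floor] = 0.0
        if weights.sum() == 0:
            # degenerate: fall back to the single best-matching signature
            cosines = [cosine_similarity(self.target, r) for r in sigs]
            weights[int(np.argmax(cosines))] = 1.0
        weights = weights / weights.sum()
        final_recon = weights @ sigs
        return SignatureRefitResults(
            model=self,
            weights=pd.Series(weights, index=self.signatures.ids, name="exposure"),
            cosine=cosine_similarity(self.target, final_recon),
            n_iterations=len(trajectory),
            objective_trajectory=trajectory,
        )


@dataclass
class SignatureRefitResults:
    """Fitted exposures with the achieved reconstruction similarity."""

    model: SignatureRefit
    weights: pd.Series
    cosine: float
    n_iterations: int
    objective_trajectory: list = field(default_factory=list)

    @property
    def exposures(self) -> pd.Series:
        """Non-zero exposures as fractions summing to 1, descending."""
        w = self.weights[self.weights > 0]
        return w.sort_values(ascending=False)

    @property
    def percentages(self) -> pd.Series:
        return self.exposures * 100.0

    def combined(self, sig_ids) -> float:
        """Combined percentage contribution of the listed signatures."""
        return combined_contribution(self.weights, sig_ids)

    def reconstruction(self) -> np.ndarray:
        return self.weights.to_numpy() @ self.model.signatures.probs

    def summary(self) -> str:
        lines = [
            "Signature refit (greedy cosine forward selection)",
            f"  catalog bins: 96   signatures tried: {len(self.model.signatures)}",
            f"  accepted iterations: {self.n_iterations}",
            f"  reconstruction cosine similarity: {self.cosine:.4f}",
            "",
            f"  {'signature':<16}{'exposure':>10}{'percent':>10}",
        ]
        for sig, w in self.exposures.items():
            lines.append(f"  {sig:<16}{w:>10.4f}{100 * w:>9.1f}%")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        df = self.weights.rename_axis("signature").reset_index()
        df["percent"] = 100.0 * df["exposure"]
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def plot_composition(self, ax=None, sample_label: str = ""):
        """Stacked horizontal bar of the percentage composition."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 1.6))
        left = 0.0
        for sig, pct in self.percentages.items():
            ax.barh([sample_label], [pct], left=left, label=sig)
            left += pct
        ax.set_xlim(0, 100)
        ax.set_xlabel("contribution to mutational composition (%)")
        ax.legend(fontsize=7, ncol=3, loc="upper right")
        return ax


def refit(catalog, signatures: SignatureMatrix, config: RefitConfig | None = None) -> SignatureRefitResults:
    """Functional entry point: ``SignatureRefit(catalog, signatures).fit()``."""
    return SignatureRefit(catalog, signatures, config).fit()


def combined_contribution(weights, sig_ids) -> float:
    """100 x the summed exposure of ``sig_ids`` (e.g. the MMR pair 6+15).

    ``weights`` is a mapping/Series of signature id -> fraction. Unknown ids
    raise ``KeyError``.
    """
    total = 0.0
    for sig in sig_ids:
        if sig not in weights:
            raise KeyError(f"unknown signature id {sig!r}")
        total += float(weights[sig])
    return 100.0 * total
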