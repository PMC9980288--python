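"""Mutational-signature refitting by forward selection with NNLS sub-solves.

A sample's normalized 96-context spectrum is approximated as a non-negative
mixture of catalog signatures (e.g. SBS1-SBS30).  Signatures are added
greedily — at each step the candidate whose inclusion most reduces the
squared reconstruction error under a non-negative least-squares fit joins
the active set — until the improvement falls below a tolerance.  Weights
below a floor (default 6%) are then zeroed and the remaining set is refit,
mirroring the discard rule of the widely used deconstruction approach.
The same objective is optimized; the sub-solver is exact NNLS, which makes
the procedure deterministic (ties broken by catalog order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .spectrum import SBS96_LABELS, Spectrum96

logger = logging.getLogger(__name__)


@dataclass
class SignatureCatalog:
    """Named signatures as probability vectors over the 96 classes.

    ``matrix`` has shape (96, n_signatures) with rows in the canonical
    class order; each column sums to 1 (tolerance 1e-6).
    """

    names: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != (96, {len(self.names)})"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("signature names must be unique")
        if np.any(self.matrix < 0):
            raise ValueError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1) > 1e-6):
            bad = [n for n, s in zip(self.names, sums) if abs(s - 1) > 1e-6]
            raise ValueError(f"signatures not normalized: {bad}")

    @classmethod
    def from_tsv(cls, path: str) -> "SignatureCatalog":
        """Read a catalog TSV: first column class labels, one column per
        signature.  Rows are reordered to canonical class order."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = set(SBS96_LABELS) - set(df.index)
        if missing:
            raise ValueError(
                f"{path}: catalog missing classes {sorted(missing)[:3]}..."
            )
        df = df.loc[list(SBS96_LABELS)]
        return cls(list(df.columns), df.to_numpy())

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            self.matrix, index=list(SBS96_LABELS), columns=self.names
        ).rename_axis("class").to_csv(path, sep="\t")


@dataclass
class SignatureExposure:
    """Refit mixture weights for one sample.

    Weights are fractions of the normalized spectrum attributed to each
    selected signature; ``unexplained`` is the remainder so that
    ``sum(weights) + unexplained == 1``.  ``reconstruction_error`` is the
    L2 distance between the normalized spectrum and the fitted mixture.
    """

    sample_id: str
    weights: dict[str, float]
    unexplained: float
    reconstruction_error: float

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        total = sum(self.weights.values()) + self.unexplained
        if abs(total - 1) > 1e-6:
            raise ValueError(f"weights + unexplained = {total}, expected 1")


def _nnls_weights(
    signatures: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, float]:
    w, _ = nnls(signatures, target)
    total = w.sum()
    if total > 1:  # mixture weights are fractions of the spectrum
        w = w / total
    err = float(np.sum((signatures @ w - target) ** 2))
    return w, err


def refit(
    spectrum: Spectrum96,
    catalog: SignatureCatalog,
    weight_floor: float = 0.06,
    tolerance: float = 1e-9,
) -> SignatureExposure:
    """Decompose a spectrum into catalog signature contributions.

    Raises on an empty spectrum.  ``weight_floor`` zeroes trace
    contributions that the greedy fit cannot support (set 0 to disable);
    after zeroing, the surviving set is refit so reported weights are the
    best non-negative fit of that set.
    """
    if spectrum.total == 0:
        raise ValueError(f"spectrum {spectrum.sample_id} is empty; cannot refit")
    if not 0 <= weight_floor < 1:
        raise ValueError("weight_floor must be in [0, 1)")
    target = spectrum.as_series().to_numpy(dtype=float)
    target = target / target.sum()
    n_sig = len(catalog.names)

    active: list[int] = []
    best_err = float(np.sum(target**2))  # error of the empty mixture
    while len(active) < n_sig:
        candidate_best: tuple[float, int, np.ndarray] | None = None
        for j in range(n_sig):
            if j in active:
                continue
            cols = active + [j]
            w, err = _nnls_weights(catalog.matrix[:, cols], target)
            if candidate_best is None or err < candidate_best[0] - 1e-15:
                candidate_best = (err, j, w)
        assert candidate_best is not None
        err, j, w = candidate_best
        if best_err - err < tolerance:
            break
        active.append(j)
        best_err = err

    weights = np.zeros(n_sig)
    if active:
        w, best_err = _nnls_weights(catalog.matrix[:, active], target)
        weights[active] = w
        if weight_floor > 0 and np.any((weights > 0) & (weights < weight_floor)):
            survivors = [j for j in active if weights[j] >= weight_floor]
            weights[:] = 0.0
            if survivors:
                w, best_err = _nnls_weights(catalog.matrix[:, survivors], target)
                weights[survivors] = w
            else:
                best_err = float(np.sum(target**2))
    selected = {
        catalog.names[j]: float(weights[j]) for j in range(n_sig) if weights[j] > 0
    }
    explained = sum(selected.values())
    return SignatureExposure(
        sample_id=spectrum.sample_id,
        weights=selected,
        unexplained=max(0.0, 1.0 - explained),
        reconstruction_error=float(np.sqrt(best_err)),
    )


def percent_sbs2(exposure: SignatureExposure, signature: str = "SBS2") -> float:
    """Percent contribution of a signature (0 if not selected)."""
    return 100.0 * exposure.weights.get(signature, 0.0)


def exposures_to_frame(exposures: list[SignatureExposure]) -> pd.DataFrame:
    """Samples x signatures weight table plus unexplained and error columns."""
    names = sorted({n for e in exposures for n in e.weights})
    rows = []
    for e in exposures:
        row = {n: e.weights.get(n, 0.0) for n in names}
        row["unexplained"] = e.unexplained
        row["reconstruction_error"] = e.reconstruction_error
        rows.append(pd.Series(row, name=e.sample_id))
    return pd.DataFrame(rows)
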