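"""Lead-covariance estimation and eigenvalue-spectrum features.

The feature vector of a record is the descending eigenvalue spectrum
lambda_1 >= ... >= lambda_8 of the 8 x 8 sample covariance
R = (1/K) X X^T of the mean-centered analysis-lead matrix X.  Under the
linear volume-conductor mixing model x(t) = A s(t) + n(t) the number of
large eigenvalues equals the number of independent cardiac sources
(about three in a clean record), while lead disconnection collapses the
spectrum (lambda_8 -> 0) and external artifacts inflate the leading
eigenvalues.  No scaling or normalisation is applied at any stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io import EcgRecord, LeadMatrix, select_leads

#: Linear eigenvalues at or below this are shown as log10 = -12 in the
#: log view (histogram pooling of numerically-zero eigenvalues).
LOG10_FLOOR = -12.0
_ZERO_LIN = 1e-12


@dataclass
class CovarianceMatrix:
    """8 x 8 sample covariance of the centered leads (ADC-count^2 units)."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (8, 8):
            raise InputError("covariance must be 8 x 8")
        scale = max(np.abs(self.entries).max(), 1.0)
        if np.abs(self.entries - self.entries.T).max() > 1e-9 * scale:
            raise InputError("covariance matrix is not symmetric within tolerance")

    @property
    def trace(self) -> float:
        return float(np.trace(self.entries))


@dataclass
class EigenSpectrum:
    """Descending eigenvalues of the lead covariance, linear scale."""

    lambdas: np.ndarray

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.lambdas.ndim != 1 or self.lambdas.size != 8:
            raise InputError("spectrum must hold exactly 8 eigenvalues")
        if np.any(np.diff(self.lambdas) > 0):
            raise InputError("eigenvalues must be sorted descending")
        if self.lambdas[-1] < 0:
            raise InputError("eigenvalues must be non-negative")

    @property
    def log10(self) -> np.ndarray:
        """log10 view; numerically-zero eigenvalues map to the -12 floor."""
        out = np.full(8, LOG10_FLOOR)
        pos = self.lambdas > _ZERO_LIN
        out[pos] = np.log10(self.lambdas[pos])
        return out

    def __getitem__(self, i: int) -> float:
        return float(self.lambdas[i])


def center_leads(matrix: LeadMatrix) -> LeadMatrix:
    """Subtract each lead's temporal mean (the only preprocessing applied)."""
    if matrix.n_samples < 2:
        raise InputError("need at least 2 samples to center")
    values = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    return LeadMatrix(values=values, centered=True)


def estimate_covariance(matrix: LeadMatrix) -> CovarianceMatrix:
    """Sample covariance R = (1/K) X X^T; the divisor is K, not K - 1."""
    if matrix.n_samples == 0:
        raise InputError("empty lead matrix")
    if not matrix.centered:
        means = matrix.values.mean(axis=1)
        scale = max(np.abs(matrix.values).max(), 1.0)
        if np.abs(means).max() > 1e-8 * scale:
            raise InputError("lead matrix must be centered first (see center_leads)")
    x = matrix.values
    cov = (x @ x.T) / matrix.n_samples
    cov = 0.5 * (cov + cov.T)  # enforce exact symmetry against fp drift
    return CovarianceMatrix(entries=cov)


def eigen_spectrum(cov: CovarianceMatrix) -> EigenSpectrum:
    """Eigenvalues of the symmetric covariance, sorted descending.

    Tiny negative values produced by floating point are clamped to zero at
    a tolerance of 1e-12 relative to the trace.
    """
    lambdas = np.linalg.eigvalsh(cov.entries)[::-1].copy()
    tol = 1e-12 * max(cov.trace, 1.0)
    if lambdas[-1] < -tol:
        raise InputError(
            f"covariance is not positive semi-definite (min eigenvalue "
            f"{lambdas[-1]:.3e})"
        )
    lambdas[lambdas < 0] = 0.0
    return EigenSpectrum(lambdas=lambdas)


def extract_features(record: EcgRecord) -> EigenSpectrum:
    """Record → spectrum: select the 8 leads, center, covariance, eigenvalues."""
    return eigen_spectrum(estimate_covariance(center_leads(select_leads(record))))


def condition_number(spectrum: EigenSpectrum) -> float:
    """kappa = lambda_1 / lambda_8; +inf when the covariance is singular."""
    if spectrum.lambdas[7] == 0.0:
        return float("inf")
    return float(spectrum.lambdas[0] / spectrum.lambdas[7])


# ---------------------------------------------------------------------------
# Feature export
# ---------------------------------------------------------------------------

def features_frame(items: list[tuple[str, EigenSpectrum]]) -> pd.DataFrame:
    """Tabulate (record_id, spectrum) pairs: linear and log10 eigenvalues + kappa."""
    rows = []
    for record_id, spectrum in items:
        row: dict[str, object] = {"record_id": record_id}
        for i in range(8):
            row[f"lambda{i + 1}"] = spectrum.lambdas[i]
        log = spectrum.log10
        for i in range(8):
            row[f"log10_lambda{i + 1}"] = log[i]
        row["kappa"] = condition_number(spectrum)
        rows.append(row)
    return pd.DataFrame(rows)


def write_features_csv(items: list[tuple[str, EigenSpectrum]], path: str) -> str:
    features_frame(items).to_csv(path, index=False)
    return path


def write_features_json(items: list[tuple[str, EigenSpectrum]], path: str) -> str:
    records = features_frame(items).to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)
    return path


def read_features_csv(path: str) -> pd.DataFrame:
    """Read a feature table written by :func:`write_features_csv`."""
    frame = pd.read_csv(path, comment="#")
    required = {"record_id"} | {f"lambda{i}" for i in range(1, 9)}
    missing = required - set(frame.columns)
    if missing:
        raise InputError(f"feature CSV {path!r} lacks columns {sorted(missing)}")
    return frame
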