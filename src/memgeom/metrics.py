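"""Decoy-discrimination and design-benchmark statistics.

Sampling protocols emit an ensemble of models, each with a score (REU or
interface score) and an RMSD to a reference.  Two summary statistics
describe whether the score discriminates near-native models:

* **enrichment** — 10 x the overlap fraction between the decile of models
  with the lowest score and the decile with the lowest RMSD.  10 means
  the top deciles coincide; 0 means they are disjoint; a random score
  gives ~1 in expectation.
* **Pnear** — the Boltzmann-weighted funnel metric

      Pnear = sum_i exp(-r_i^2/lambda^2) exp(-E_i/kT) / sum_i exp(-E_i/kT)

  in [0, 1]: 1 when every thermally relevant model sits at the reference
  conformation, ~0 when the low-energy models are far from it.  Energies
  are shifted by their minimum before exponentiation, which leaves the
  metric unchanged and avoids overflow.

The design-benchmark statistics compare a designed sequence with the
native over a set of positions: plain sequence recovery, per-amino-acid
recovery relative to the 1/20 random-guess background, and the KL
divergence of the designed amino-acid composition from the native one.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import rel_entr

__all__ = ["EnsembleTable", "DesignComparison", "enrichment", "pnear",
           "sequence_recovery", "nonrandom_recovery", "kl_divergence",
           "cumulative_rmsd", "AMINO_ACIDS"]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class EnsembleTable:
    """Per-model (score, RMSD) pairs from a sampling run."""

    model_id: np.ndarray
    score: np.ndarray
    rmsd: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.model_id)
        if n < 2:
            raise ValueError("ensemble needs at least two models")
        if len(self.score) != n or len(self.rmsd) != n:
            raise ValueError("model_id, score and rmsd must have equal length")
        if not (np.all(np.isfinite(self.score)) and np.all(np.isfinite(self.rmsd))):
            raise ValueError("scores and RMSDs must be finite")

    def __len__(self) -> int:
        return len(self.model_id)

    @classmethod
    def from_arrays(cls, score, rmsd, model_id=None) -> "EnsembleTable":
        score = np.asarray(score, dtype=float)
        rmsd = np.asarray(rmsd, dtype=float)
        if model_id is None:
            model_id = np.arange(len(score))
        return cls(model_id=np.asarray(model_id), score=score, rmsd=rmsd)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EnsembleTable":
        cols = {c.lower(): c for c in df.columns}
        score_col = next((cols[k] for k in ("score", "total_score", "energy",
                                            "interface_score") if k in cols), None)
        rmsd_col = next((cols[k] for k in ("rmsd", "irmsd", "rms") if k in cols), None)
        if score_col is None or rmsd_col is None:
            raise ValueError(
                f"table must have score and rmsd columns, found {list(df.columns)}")
        model_col = next((cols[k] for k in ("model_id", "model", "description",
                                            "tag") if k in cols), None)
        ids = df[model_col].to_numpy() if model_col else np.arange(len(df))
        return cls.from_arrays(df[score_col].to_numpy(), df[rmsd_col].to_numpy(), ids)

    @classmethod
    def from_file(cls, path) -> "EnsembleTable":
        """Read a whitespace- or comma-separated score/RMSD table.

        A header naming the columns (score/energy, rmsd, optional model id)
        is used when present; a headerless two- or three-column file is
        taken as (score, rmsd[, model_id])."""
        text = Path(path).read_text()
        sep = "," if "," in text.splitlines()[0] else r"\s+"
        df = pd.read_csv(io.StringIO(text), sep=sep)
        lowered = {str(c).lower() for c in df.columns}
        if not ({"score", "total_score", "energy", "interface_score"} & lowered
                and {"rmsd", "irmsd", "rms"} & lowered):
            df = pd.read_csv(io.StringIO(text), sep=sep, header=None)
            df.columns = ["score", "rmsd", "model_id"][:len(df.columns)]
        return cls.from_dataframe(df)


def _top_k_indices(values: np.ndarray, model_id: np.ndarray, k: int) -> set:
    """Indices of the k smallest values; ties broken by model_id (stable)."""
    order = np.lexsort((model_id, values))
    return set(order[:k].tolist())


def enrichment(table: EnsembleTable, fraction: float = 0.1) -> float:
    """Top-decile overlap statistic in [0, 10].

    E = (1/fraction) * |S ∩ R| / k with S the k = ceil(fraction*N) lowest
    scores and R the k lowest RMSDs.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(table)
    if n * fraction < 1:
        raise ValueError(f"ensemble of {n} models too small for fraction {fraction}")
    k = math.ceil(fraction * n)
    best_score = _top_k_indices(table.score, table.model_id, k)
    best_rmsd = _top_k_indices(table.rmsd, table.model_id, k)
    return (1.0 / fraction) * len(best_score & best_rmsd) / k


def pnear(table: EnsembleTable, lambda_: float = 2.0, kT: float = 1.0) -> float:
    """Boltzmann-weighted funnel metric in [0, 1].

    lambda_ sets the RMSD scale of "near-native" (Å); kT the energy scale
    (same units as the scores).
    """
    if lambda_ <= 0 or kT <= 0:
        raise ValueError("lambda_ and kT must be positive")
    e = table.score - table.score.min()
    w = np.exp(-e / kT)
    return float(np.sum(w * np.exp(-(table.rmsd / lambda_) ** 2)) / np.sum(w))


def cumulative_rmsd(table: EnsembleTable):
    """Empirical CDF of the ensemble RMSDs.

    Returns (x, cdf): sorted unique RMSD values and the right-continuous
    cumulative fraction of models at or below each.
    """
    x, counts = np.unique(table.rmsd, return_counts=True)
    return x, np.cumsum(counts) / len(table)


# ---------------------------------------------------------------------------
# design-benchmark statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignComparison:
    """Native and designed sequences over the designable positions."""

    native: str
    designed: str

    def __post_init__(self) -> None:
        if len(self.native) != len(self.designed):
            raise ValueError("native and designed sequences differ in length")
        bad = set(self.native + self.designed) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard amino acid letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.native)


def _mask_indices(dc: DesignComparison, mask) -> np.ndarray:
    if mask is None:
        idx = np.arange(len(dc))
    else:
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask.astype(int)
    if idx.size == 0:
        raise ValueError("position mask is empty")
    return idx


def sequence_recovery(dc: DesignComparison, mask=None) -> float:
    """Fraction of native residues recovered over the (masked) positions."""
    idx = _mask_indices(dc, mask)
    return float(np.mean([dc.native[i] == dc.designed[i] for i in idx]))


def nonrandom_recovery(dc: DesignComparison, mask=None) -> dict[str, float]:
    """Per-amino-acid recovery rate relative to the 1/20 random background.

    1.0 means recovered no better than guessing; 20.0 means always
    recovered.  Amino acids absent from the native positions are omitted.
    """
    idx = _mask_indices(dc, mask)
    out: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        positions = [i for i in idx if dc.native[i] == aa]
        if not positions:
            continue
        rate = np.mean([dc.designed[i] == aa for i in positions])
        out[aa] = float(rate / (1.0 / 20.0))
    return out


def kl_divergence(dc: DesignComparison, mask=None, pseudocount: float = 1e-4) -> float:
    """KL divergence D(designed || native) of amino-acid compositions, nats.

    A small pseudocount keeps both 20-letter distributions strictly
    positive; 0 iff the compositions coincide (up to the smoothing).
    """
    idx = _mask_indices(dc, mask)

    def _dist(seq: str) -> np.ndarray:
        counts = np.array([sum(seq[i] == aa for i in idx) for aa in AMINO_ACIDS],
                          dtype=float) + pseudocount
        return counts / counts.sum()

    return float(rel_entr(_dist(dc.designed), _dist(dc.native)).sum())
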