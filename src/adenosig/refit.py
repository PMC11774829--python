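"""Signature refitting: decompose a 96-channel catalogue into exposures.

Given a reference matrix ``P`` (96 classes x K signatures, columns summing
to one) and a sample's normalised catalogue ``v``, refitting finds the
exposure vector ``e`` on the K-simplex minimising the Euclidean
reconstruction distance ``||v - P e||``. The optimiser is simulated
annealing over the simplex — proposals move a random amount of mass
between two randomly chosen signatures, accepted by the Metropolis rule
under a geometric cooling schedule — followed by a pairwise projected
coordinate-descent polish. For small K an exhaustive lattice search over
the simplex is provided as an independent oracle.

Refitting operates on proportion vectors, so exposures are reported as the
fraction of a sample's mutations attributed to each signature; the result
is invariant to scaling the catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalogue import CLASSES_96, Catalogue96
from .errors import ConfigurationError, RefitError

__all__ = [
    "SignatureMatrix",
    "ExposureVector",
    "AnnealingParams",
    "load_signature_matrix",
    "write_signature_tsv",
    "catalogue_to_vector",
    "refit_exposures",
    "refit_catalogue",
    "refit_oracle_grid",
    "combined_exposure",
    "bootstrap_exposures",
]

#: Samples with fewer SNVs than this are refit but flagged low-confidence.
LOW_CONFIDENCE_SNV_FLOOR = 50


@dataclass(frozen=True)
class SignatureMatrix:
    """96 x K matrix of class probabilities, one column per signature."""

    names: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "names", tuple(self.names))
        if probs.ndim != 2 or probs.shape[0] != 96:
            raise ValueError(f"probs must be 96 x K, got {probs.shape}")
        if probs.shape[1] != len(self.names):
            raise ValueError("number of names does not match number of columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("signature names must be unique")
        if probs.shape[1] < 1:
            raise ValueError("need at least one signature")
        if np.any(probs < 0) or not np.all(np.isfinite(probs)):
            raise ValueError("probabilities must be finite and non-negative")
        colsums = probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise ValueError("each signature column must sum to 1 (within 1e-6)")

    @property
    def k(self) -> int:
        return self.probs.shape[1]

    def subset(self, names: Sequence[str]) -> "SignatureMatrix":
        """Select signatures, preserving the requested order."""
        idx = []
        for n in names:
            if n not in self.names:
                raise KeyError(f"unknown signature {n!r}")
            idx.append(self.names.index(n))
        return SignatureMatrix(tuple(names), self.probs[:, idx])

    def column(self, name: str) -> np.ndarray:
        return self.probs[:, self.names.index(name)]


@dataclass(frozen=True)
class ExposureVector:
    """Simplex-constrained per-signature proportions for one sample."""

    names: tuple[str, ...]
    exposures: np.ndarray
    reconstruction_error: float  # Euclidean distance ||v - P e||
    n_snv: int | None = None

    def __post_init__(self) -> None:
        exp = np.asarray(self.exposures, dtype=float)
        object.__setattr__(self, "exposures", exp)
        object.__setattr__(self, "names", tuple(self.names))
        if exp.shape != (len(self.names),):
            raise ValueError("exposures length does not match names")
        if np.any(exp < -1e-12):
            raise ValueError("negative exposure")
        if abs(exp.sum() - 1.0) > 1e-6:
            raise ValueError(f"exposures must sum to 1, got {exp.sum()}")
        if self.reconstruction_error < 0:
            raise ValueError("negative reconstruction error")

    @property
    def low_confidence(self) -> bool:
        return self.n_snv is not None and self.n_snv < LOW_CONFIDENCE_SNV_FLOOR

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.exposures.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.exposures[self.names.index(name)])


@dataclass(frozen=True)
class AnnealingParams:
    """Simulated-annealing schedule.

    The schedule is geometric: the temperature after step ``t`` is
    ``initial_temperature * cooling_factor**t``. Each proposal moves a mass
    ``delta ~ Uniform(0, proposal_step_size)`` from one random signature to
    another, clipped at zero. The best exposure over ``restarts``
    independent runs is returned, after a deterministic coordinate-descent
    polish.
    """

    initial_temperature: float = 0.01
    cooling_factor: float = 0.995
    steps: int = 10_000
    proposal_step_size: float = 0.1
    restarts: int = 5
    seed: int = 1337

    def __post_init__(self) -> None:
        if not 0 < self.cooling_factor < 1:
            raise ConfigurationError("cooling_factor must be in (0, 1)")
        if self.steps < 1:
            raise ConfigurationError("steps must be >= 1")
        if not 0 < self.proposal_step_size <= 1:
            raise ConfigurationError("proposal_step_size must be in (0, 1]")
        if self.restarts < 1:
            raise ConfigurationError("restarts must be >= 1")
        if self.initial_temperature <= 0:
            raise ConfigurationError("initial_temperature must be positive")


def load_signature_matrix(
    path: str | Path, subset: Sequence[str] | None = None
) -> SignatureMatrix:
    """Load a COSMIC-style 96-row signature TSV.

    Two dialects are auto-detected: a single class column in bracket
    notation (``A[C>A]A``), or the split "Type"/"Subtype" COSMIC layout
    where Type is ``C>A`` and Subtype the trinucleotide ``ACA``. Rows are
    reordered to canonical class order; columns within 1e-3 of unit sum are
    renormalised, anything further off is an error.
    """
    df = pd.read_csv(path, sep="\t")
    cols_lower = {c.lower(): c for c in df.columns}
    if "type" in cols_lower and ("subtype" in cols_lower or "sub_type" in cols_lower):
        type_col = cols_lower["type"]
        sub_col = cols_lower.get("subtype", cols_lower.get("sub_type"))
        labels = [
            f"{s[0]}[{t}]{s[2]}" for t, s in zip(df[type_col], df[sub_col])
        ]
        df = df.drop(columns=[type_col, sub_col])
        df.index = labels
    else:
        # first column whose values look like bracket-notation classes
        class_col = None
        for c in df.columns:
            vals = df[c].astype(str)
            if vals.str.match(r"^[ACGT]\[[ACGT]>[ACGT]\][ACGT]$").all():
                class_col = c
                break
        if class_col is None:
            raise ValueError("no class column found (bracket or Type/Subtype dialect)")
        df.index = df[class_col].astype(str)
        df = df.drop(columns=[class_col])
    missing = set(CLASSES_96) - set(df.index)
    if missing:
        raise ValueError(f"signature TSV is missing {len(missing)} class rows")
    df = df.loc[list(CLASSES_96)]
    probs = df.to_numpy(dtype=float)
    colsums = probs.sum(axis=0)
    bad = np.abs(colsums - 1.0) > 1e-3
    if np.any(bad):
        names_bad = [df.columns[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"signature column(s) do not sum to 1: {names_bad}")
    probs = probs / colsums
    mat = SignatureMatrix(tuple(df.columns), probs)
    if subset is not None:
        mat = mat.subset(subset)
    return mat


def write_signature_tsv(matrix: SignatureMatrix, path: str | Path) -> None:
    """Write a signature matrix in bracket-notation TSV."""
    out = pd.DataFrame(matrix.probs, columns=list(matrix.names))
    out.insert(0, "class", list(CLASSES_96))
    out.to_csv(path, sep="\t", index=False)


def catalogue_to_vector(catalogue: Catalogue96) -> np.ndarray:
    """Normalise a catalogue to a 96-proportion vector."""
    total = catalogue.snv_total
    if total == 0:
        raise RefitError(
            f"{catalogue.sample_id}: signature proportions are undefined "
            "for a sample with zero SNVs"
        )
    return catalogue.as_array() / total


def _objective_terms(vector: np.ndarray, probs: np.ndarray):
    """Precompute the quadratic form: f(e) = v.v - 2 c.e + e' G e."""
    gram = probs.T @ probs
    c = probs.T @ vector
    vv = float(vector @ vector)
    return gram, c, vv


def _polish(e: np.ndarray, gram: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Pairwise projected coordinate descent on the simplex.

    For each signature pair (i, j) the optimal mass transfer ``t`` (from i
    to j) has a closed form for the quadratic objective; ``t`` is clipped so
    both exposures stay non-negative. Sweeps repeat until no pair improves.
    """
    k = len(e)
    e = e.copy()
    h = gram @ e
    for _ in range(500):
        improved = False
        for i in range(k):
            for j in range(i + 1, k):
                denom = gram[i, i] - 2.0 * gram[i, j] + gram[j, j]
                if denom <= 1e-15:
                    continue
                t = ((c[j] - c[i]) - (h[j] - h[i])) / denom
                t = min(max(t, -e[j]), e[i])
                if abs(t) < 1e-15:
                    continue
                delta_f = (-2.0 * (c[j] - c[i]) + 2.0 * (h[j] - h[i])) * t + denom * t * t
                if delta_f < -1e-16:
                    e[i] -= t
                    e[j] += t
                    h = h + t * (gram[:, j] - gram[:, i])
                    improved = True
        if not improved:
            break
    np.clip(e, 0.0, None, out=e)
    e /= e.sum()
    return e


def _anneal_once(
    gram: np.ndarray,
    c: np.ndarray,
    vv: float,
    e0: np.ndarray,
    params: AnnealingParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """One annealing run; returns (best exposures, best squared objective)."""
    k = len(e0)
    e = e0.copy()
    h = gram @ e
    f = vv - 2.0 * float(c @ e) + float(e @ h)
    best_e, best_f = e.copy(), f
    n = params.steps
    # pre-drawn randomness keeps the hot loop in plain python scalars
    src = rng.integers(0, k, size=n).tolist()
    dst = rng.integers(0, k, size=n).tolist()
    deltas = (rng.random(size=n) * params.proposal_step_size).tolist()
    accept_u = rng.random(size=n).tolist()
    log_u = np.log(np.maximum(accept_u, 1e-300)).tolist()
    temp = params.initial_temperature
    cool = params.cooling_factor
    g = gram
    for step in range(n):
        i = src[step]
        j = dst[step]
        if i == j:
            temp *= cool
            continue
        t = deltas[step]
        if t > e[i]:
            t = e[i]
        if t == 0.0:
            temp *= cool
            continue
        denom = g[i, i] - 2.0 * g[i, j] + g[j, j]
        delta_f = (-2.0 * (c[j] - c[i]) + 2.0 * (h[j] - h[i])) * t + denom * t * t
        if delta_f <= 0.0 or delta_f < -temp * log_u[step]:
            e[i] -= t
            e[j] += t
            h = h + t * (g[:, j] - g[:, i])
            f += delta_f
            if f < best_f:
                best_f = f
                best_e = e.copy()
        temp *= cool
    return best_e, best_f


def refit_exposures(
    vector: np.ndarray,
    signatures: SignatureMatrix,
    params: AnnealingParams | None = None,
    n_snv: int | None = None,
    objective: str = "euclidean",
) -> ExposureVector:
    """Fit simplex-constrained exposures to a 96-proportion vector.

    The default objective is the Euclidean reconstruction distance; a
    cosine-distance variant (``objective="cosine"``) is available for
    sensitivity analysis. Results are bit-reproducible for a fixed
    ``params.seed``.
    """
    params = params or AnnealingParams()
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (96,):
        raise ValueError(f"expected a 96-vector, got shape {vector.shape}")
    if not np.all(np.isfinite(vector)):
        raise ValueError("non-finite entries in input vector")
    if not np.all(np.isfinite(signatures.probs)):
        raise ValueError("non-finite entries in signature matrix")
    if objective not in ("euclidean", "cosine"):
        raise ConfigurationError(f"unknown objective {objective!r}")
    if objective == "cosine":
        return _refit_cosine(vector, signatures, params, n_snv)

    probs = signatures.probs
    k = signatures.k
    gram, c, vv = _objective_terms(vector, probs)
    rng = np.random.default_rng(params.seed)
    best_e: np.ndarray | None = None
    best_f = np.inf
    for restart in range(params.restarts):
        e0 = np.full(k, 1.0 / k) if restart == 0 else rng.dirichlet(np.ones(k))
        e, f = _anneal_once(gram, c, vv, e0, params, rng)
        if f < best_f:
            best_f, best_e = f, e
    assert best_e is not None
    e = _polish(best_e, gram, c)
    err = float(np.linalg.norm(vector - probs @ e))
    return ExposureVector(signatures.names, e, err, n_snv=n_snv)


def _refit_cosine(vector, signatures, params, n_snv):
    """Cosine-distance refit: same proposal scheme, full objective per step."""
    probs = signatures.probs
    k = signatures.k
    vnorm = np.linalg.norm(vector)

    def cosdist(e):
        recon = probs @ e
        d = np.linalg.norm(recon) * vnorm
        return 1.0 - float(recon @ vector) / d if d > 0 else 1.0

    rng = np.random.default_rng(params.seed)
    best_e, best_f = None, np.inf
    for restart in range(params.restarts):
        e = np.full(k, 1.0 / k) if restart == 0 else rng.dirichlet(np.ones(k))
        f = cosdist(e)
        temp = params.initial_temperature
        for _ in range(params.steps):
            i, j = rng.integers(0, k, size=2)
            if i != j:
                t = min(rng.random() * params.proposal_step_size, e[i])
                if t > 0:
                    cand = e.copy()
                    cand[i] -= t
                    cand[j] += t
                    fc = cosdist(cand)
                    if fc <= f or rng.random() < np.exp(-(fc - f) / temp):
                        e, f = cand, fc
            temp *= params.cooling_factor
        if f < best_f:
            best_e, best_f = e.copy(), f
    err = float(np.linalg.norm(vector - probs @ best_e))
    return ExposureVector(signatures.names, best_e, err, n_snv=n_snv)


def refit_catalogue(
    catalogue: Catalogue96,
    signatures: SignatureMatrix,
    params: AnnealingParams | None = None,
) -> ExposureVector:
    """Convenience wrapper: normalise a catalogue and refit it."""
    vector = catalogue_to_vector(catalogue)
    return refit_exposures(vector, signatures, params, n_snv=catalogue.snv_total)


def _simplex_lattice(k: int, n: int):
    """Yield all length-k integer compositions of n in lexicographic order."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _simplex_lattice(k - 1, n - first):
            yield (first, *rest)


def refit_oracle_grid(
    vector: np.ndarray,
    signatures: SignatureMatrix,
    step: float = 0.01,
) -> ExposureVector:
    """Exhaustive minimiser over the simplex lattice of the given step.

    Exact within the lattice; intended as an independent oracle for the
    annealer on small problems, so K is capped at 4. Ties resolve to the
    lexicographically first lattice point.
    """
    k = signatures.k
    if k > 4:
        raise ConfigurationError("grid oracle supports K <= 4 only")
    n = int(round(1.0 / step))
    vector = np.asarray(vector, dtype=float)
    points = np.array(list(_simplex_lattice(k, n)), dtype=float) / n
    best_err = np.inf
    best_row: np.ndarray | None = None
    chunk = 50_000
    for start in range(0, len(points), chunk):
        block = points[start : start + chunk]
        recon = block @ signatures.probs.T
        errs = np.linalg.norm(recon - vector, axis=1)
        idx = int(np.argmin(errs))
        if errs[idx] < best_err:  # strict: keeps the lexicographically first tie
            best_err = float(errs[idx])
            best_row = block[idx]
    assert best_row is not None
    return ExposureVector(signatures.names, best_row, best_err)


def combined_exposure(exposures: ExposureVector, group: Sequence[str]) -> float:
    """Sum of the named signatures' exposures (e.g. SBS18 + SBS36)."""
    total = 0.0
    for name in group:
        if name not in exposures.names:
            raise KeyError(f"unknown signature {name!r}")
        total += exposures[name]
    return total


def bootstrap_exposures(
    catalogue: Catalogue96,
    signatures: SignatureMatrix,
    params: AnnealingParams | None = None,
    n_boot: int = 100,
) -> pd.DataFrame:
    """Multinomial bootstrap of a catalogue's exposures.

    Resamples the catalogue ``n_boot`` times with its own empirical class
    frequencies, refits each replicate, and reports per-signature quantiles.
    Deterministic for a fixed ``params.seed``. A stability diagnostic for
    low-burden samples.
    """
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    params = params or AnnealingParams()
    vector = catalogue_to_vector(catalogue)
    total = catalogue.snv_total
    rng = np.random.default_rng(params.seed)
    child_seeds = np.random.SeedSequence(params.seed).generate_state(n_boot) % (2**31)
    draws = np.empty((n_boot, signatures.k))
    for b in range(n_boot):
        resampled = rng.multinomial(total, vector)
        rep_params = AnnealingParams(
            initial_temperature=params.initial_temperature,
            cooling_factor=params.cooling_factor,
            steps=params.steps,
            proposal_step_size=params.proposal_step_size,
            restarts=params.restarts,
            seed=int(child_seeds[b]),
        )
        fit = refit_exposures(resampled / total, signatures, rep_params, n_snv=total)
        draws[b] = fit.exposures
    return pd.DataFrame(
        {
            "signature": list(signatures.names),
            "mean": draws.mean(axis=0),
            "q025": np.quantile(draws, 0.025, axis=0),
            "q50": np.quantile(draws, 0.5, axis=0),
            "q975": np.quantile(draws, 0.975, axis=0),
        }
    ).set_index("signature")


def write_exposures_tsv(exposures: dict[str, ExposureVector], path: str | Path) -> None:
    """Long-format exposure TSV, one row per (sample, signature)."""
    rows = []
    for sid, exp in exposures.items():
        for name, value in exp.as_dict().items():
            rows.append(
                {
                    "sample_id": sid,
                    "signature": name,
                    "exposure": value,
                    "reconstruction_error": exp.reconstruction_error,
                    "n_snv": exp.n_snv,
                    "low_confidence": exp.low_confidence,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
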