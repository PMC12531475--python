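"""Generators of binary rating matrices with known agreement structure.

Three study designs are emulated:

* :func:`simulate_common_correlation` -- exchangeable raters.  Each
  patient receives a latent positive probability drawn from a beta
  distribution with mean ``prevalence`` and intraclass correlation
  ``icc``; raters are conditionally independent.  The intraclass kappa
  (pooled-marginal chance) is a consistent estimator of ``icc`` under this
  model, and pairwise agreement satisfies
  ``qo = 2 pi (1 - pi) (1 - icc)``.
* :func:`simulate_rater_shift` -- raters with their own rating styles.  A
  latent equicorrelated Gaussian score per patient is dichotomized at
  rater-specific cutpoints matching requested per-rater positive rates;
  marginal heterogeneity opens a gap between rater-marginal and
  pooled-marginal kappas.
* :func:`simulate_intra_rater` -- one (or more) observer(s) re-assessing
  each patient on several occasions; replicates are exchangeable within
  patient, so occasion labels carry no information.

All generators require an explicit seed and are deterministic given the
spec; :func:`write_simulation` saves the wide CSV together with a JSON
sidecar recording the generating spec.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import AgreementDataError, RatingsMatrix, write_wide

__all__ = [
    "SimulationSpec",
    "simulate_common_correlation",
    "simulate_rater_shift",
    "simulate_intra_rater",
    "write_simulation",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a simulated agreement study.

    ``icc`` is the within-patient correlation of ratings (0 = independent
    raters, 1 = all raters copy the patient's true state).  For
    :func:`simulate_rater_shift`, ``rater_marginals`` gives each rater's
    positive rate and ``icc`` acts on the latent Gaussian scale.
    """

    n_patients: int
    n_raters: int
    prevalence: float = 0.5
    icc: float = 0.0
    occasions: int = 1
    seed: int | None = None
    rater_marginals: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise AgreementDataError("simulation requires an explicit seed")
        if not 0 <= self.icc <= 1:
            raise AgreementDataError("icc must lie in [0, 1]")
        if not 0 < self.prevalence < 1:
            raise AgreementDataError("prevalence must lie in (0, 1)")
        if self.n_patients < 1 or self.n_raters < 1 or self.occasions < 1:
            raise AgreementDataError("sizes must be positive")
        if self.rater_marginals is not None:
            if len(self.rater_marginals) != self.n_raters:
                raise AgreementDataError("need one marginal per rater")
            if not all(0 < p < 1 for p in self.rater_marginals):
                raise AgreementDataError("rater marginals must lie in (0, 1)")


def _latent_probabilities(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-patient positive probabilities: beta with mean pi, correlation icc."""
    pi = spec.prevalence
    if spec.icc == 0:
        return np.full(spec.n_patients, pi)
    if spec.icc == 1:
        return (rng.random(spec.n_patients) < pi).astype(float)
    s = (1 - spec.icc) / spec.icc
    return rng.beta(pi * s, (1 - pi) * s, size=spec.n_patients)


def _to_matrix(values: np.ndarray, occasions: int = 1) -> RatingsMatrix:
    n, r = values.shape[:2]
    patients = [f"p{i + 1:04d}" for i in range(n)]
    raters = [f"r{j + 1}" for j in range(r)]
    records = []
    for i, p in enumerate(patients):
        for j, rt in enumerate(raters):
            if occasions == 1:
                records.append((p, rt, 1, int(values[i, j])))
            else:
                for k in range(occasions):
                    records.append((p, rt, k + 1, int(values[i, j, k])))
    frame = pd.DataFrame(records,
                         columns=["patient_id", "rater_id", "occasion", "rating"])
    return RatingsMatrix(frame)


def simulate_common_correlation(spec: SimulationSpec) -> RatingsMatrix:
    """Exchangeable-rater ratings with a beta-mixed positive probability."""
    rng = np.random.default_rng(spec.seed)
    p = _latent_probabilities(spec, rng)
    ratings = rng.random((spec.n_patients, spec.n_raters)) < p[:, None]
    return _to_matrix(ratings.astype(int))


def simulate_rater_shift(spec: SimulationSpec) -> RatingsMatrix:
    """Latent-threshold ratings with rater-specific cutpoints.

    Patient i carries an equicorrelated standard-normal vector
    (correlation ``icc``); rater j flags positive when their coordinate
    falls below the cutpoint Phi^{-1}(pi_j).
    """
    marg = spec.rater_marginals
    if marg is None:
        marg = [spec.prevalence] * spec.n_raters
    rng = np.random.default_rng(spec.seed)
    r = spec.icc
    common = rng.standard_normal((spec.n_patients, 1))
    noise = rng.standard_normal((spec.n_patients, spec.n_raters))
    z = np.sqrt(r) * common + np.sqrt(1 - r) * noise
    cut = stats.norm.ppf(np.asarray(marg))
    return _to_matrix((z < cut[None, :]).astype(int))


def simulate_intra_rater(spec: SimulationSpec) -> RatingsMatrix:
    """Repeated assessments: conditionally iid replicates per patient.

    Every rating (any rater, any occasion) is an independent Bernoulli
    draw from the patient's latent probability, so occasions are
    exchangeable and relabeling them leaves all statistics invariant in
    distribution.
    """
    if spec.occasions < 2:
        raise AgreementDataError("intra-rater designs need at least two occasions")
    rng = np.random.default_rng(spec.seed)
    p = _latent_probabilities(spec, rng)
    shape = (spec.n_patients, spec.n_raters, spec.occasions)
    ratings = rng.random(shape) < p[:, None, None]
    return _to_matrix(ratings.astype(int), occasions=spec.occasions)


def write_simulation(m: RatingsMatrix, spec: SimulationSpec, path) -> None:
    """Save a single-occasion matrix as wide CSV plus a provenance sidecar."""
    path = Path(path)
    write_wide(m, path)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps(dataclasses.asdict(spec), indent=2, default=list))
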