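"""End-to-end scaling of free-space self-avoiding walks.

Sanity check of the chain generator: in free space (no confinement, no
chirality bias) the mean squared end-to-end length of a self-avoiding walk
scales as r^2 ~ n^(2 nu) with the Flory exponent nu ~ 0.588; an ideal
(phantom) chain gives nu = 1/2 exactly.  Including the connector-cylinder
excluded volume stiffens the chain and can only increase the measured
exponent at these chain lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .params import ModelParams
from .saw import grow_single_chain

__all__ = ["ScalingFit", "grow_free_saw", "fit_scaling", "DEFAULT_LENGTHS"]

DEFAULT_LENGTHS = (50, 70, 90, 110, 130, 150)


@dataclass(frozen=True)
class ScalingFit:
    exponent: float  # nu in r ~ n^nu
    prefactor: float  # um
    exponent_stderr: float
    lengths: tuple
    replicates_per_n: int
    with_cylinder_excluded_volume: bool
    phantom: bool
    mean_sq_r: tuple  # <r^2> per length, um^2


def grow_free_saw(
    n_beads: int,
    params: ModelParams,
    rng,
    with_cylinder: bool = True,
    phantom: bool = False,
) -> np.ndarray:
    """One unconfined chain with the model's excluded-volume rules
    (optionally including the connector cylinders) and no chirality bias."""
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    return grow_single_chain(
        n_beads, params, rng, with_cylinder=with_cylinder, phantom=phantom
    )


def fit_scaling(
    lengths=DEFAULT_LENGTHS,
    reps: int = 1000,
    params: ModelParams | None = None,
    with_cylinder: bool = True,
    rng=None,
    phantom: bool = False,
) -> ScalingFit:
    """Least-squares fit of log <r^2> against log n over free-space chains.

    The scaling exponent is half the fitted slope.  ``reps`` chains are
    grown per length.
    """
    lengths = sorted(set(int(x) for x in lengths))
    if len(lengths) < 3:
        raise ValueError("need at least 3 distinct chain lengths")
    if reps < 10:
        raise ValueError("reps must be >= 10")
    if params is None:
        from .params import default_params

        params = default_params()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    msr = []
    for n in lengths:
        r2 = np.empty(reps)
        for i in range(reps):
            chain = grow_free_saw(n, params, rng, with_cylinder=with_cylinder, phantom=phantom)
            r2[i] = ((chain[-1] - chain[0]) ** 2).sum()
        msr.append(r2.mean())
    msr = np.asarray(msr)
    fit = sps.linregress(np.log(lengths), np.log(msr))
    return ScalingFit(
        exponent=float(fit.slope / 2.0),
        prefactor=float(np.exp(fit.intercept / 2.0)),
        exponent_stderr=float(fit.stderr / 2.0),
        lengths=tuple(lengths),
        replicates_per_n=reps,
        with_cylinder_excluded_volume=bool(with_cylinder and not phantom),
        phantom=phantom,
        mean_sq_r=tuple(float(x) for x in msr),
    )
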