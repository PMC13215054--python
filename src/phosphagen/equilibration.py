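"""Instantaneous adenylate-kinase / arginine-kinase equilibration.

After every production/consumption update the two kinases are assumed to
re-equilibrate instantly:

    K_Ad [ATP][AMP] = [ADP]^2        (AK:   AMP + ATP <-> 2 ADP)
    K_Ph [ADP][ArgP] = [ATP][Arg]    (ArgK: ADP + ArgP <-> ATP + Arg)

The solver parameterizes the update by the two reaction extents, which
makes the adenine pool (ATP+ADP+AMP), the guanidino pool (Arg+ArgP) and
the phosphoryl tally (3 ATP + 2 ADP + AMP + ArgP) exactly conserved by
construction; Pi is untouched.  A damped Newton iteration on the two
equilibrium residuals is used, falling back to alternating exact
single-reaction bisections if Newton stalls or leaves the feasible box
(all species >= 0).  Without a phosphagen only the AK relation is
enforced and Arg/ArgP are returned unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._kernels import _equilibrate_kernel
from .core import EquilibriumConstants, InvalidParameterError, MetabolicState

__all__ = [
    "EquilibrationOptions",
    "ConvergenceError",
    "InfeasibleStateError",
    "equilibrate",
]


class ConvergenceError(RuntimeError):
    """Equilibration failed to reach tolerance; carries final residuals."""

    def __init__(self, msg: str, residuals=None):
        super().__init__(msg)
        self.residuals = residuals


class InfeasibleStateError(ValueError):
    """No non-negative equilibrium reachable from the given state."""


@dataclass(frozen=True)
class EquilibrationOptions:
    """tol: relative residual tolerance; max_iter: Newton iteration (and
    fallback sweep) limit; enforce_phosphagen: enforce the ArgK relation."""

    tol: float = 1e-10
    max_iter: int = 100
    enforce_phosphagen: bool = True

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise InvalidParameterError("tol must be > 0")
        if self.max_iter < 1:
            raise InvalidParameterError("max_iter must be >= 1")


def equilibrate(
    state: MetabolicState,
    k: EquilibriumConstants = EquilibriumConstants(),
    opt: EquilibrationOptions = EquilibrationOptions(),
) -> MetabolicState:
    """Project a state onto the AK (and optionally ArgK) equilibrium manifold.

    Conserves the adenine pool, the guanidino pool and the phosphoryl
    tally exactly; Pi is unchanged.  Raises :class:`ConvergenceError` if
    the residual tolerance is not met within the iteration budget and
    :class:`InfeasibleStateError` on negative inputs.
    """
    atp, adp, amp, arg, argp, st, r1, r2, _ = _equilibrate_kernel(
        state.atp, state.adp, state.amp, state.arg, state.argp,
        k.k_ad, k.k_ph, opt.enforce_phosphagen, opt.tol, opt.max_iter,
    )
    if st == 2:
        raise InfeasibleStateError("negative concentration in equilibration input")
    if st != 0:
        raise ConvergenceError(
            f"equilibration did not converge (residuals {r1:.3e}, {r2:.3e})",
            residuals=(r1, r2),
        )
    if opt.enforce_phosphagen:
        return MetabolicState(atp=atp, adp=adp, amp=amp, arg=arg, argp=argp, pi=state.pi)
    # ArgK not enforced: Arg/ArgP must come back bit-identical
    return MetabolicState(atp=atp, adp=adp, amp=amp,
                          arg=state.arg, argp=state.argp, pi=state.pi)
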