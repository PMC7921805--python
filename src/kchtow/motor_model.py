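"""Single-motor mechanics and two-team cargo force balance.

The cargo (the microtubule cage enclosing the sperm cells) is pulled by two
antagonistic teams of non-processive kinesin-14 (KCH) motors drawn from one
shared pool of ``N`` motors.  Motors bound to apexward-carrying microtubules
form the *forward* team, motors bound to grain-ward-carrying microtubules the
*backward* team.  Each single motor is characterised by a linear
force-velocity relation with stall force ``F_s``, a slow backslip branch
above stall, a constant binding rate ``pi_0`` and an unbinding rate that
grows exponentially with load on the scale of the detachment force ``F_d``.

When ``n_plus`` and ``n_minus`` motors are bound, the instantaneous force
balance of the rigid-coupling mean-field model gives a cargo force ``F_c``
shared equally within each team and a common cargo velocity ``v_c``
satisfying ``v_c = v_plus(F_c/n_plus) = -v_minus(F_c/n_minus)``.

Units are pN, um and s throughout; nm/s appears only at reporting
boundaries (see :mod:`kchtow.track_analysis`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import NamedTuple

__all__ = [
    "MotorTeamParams",
    "TugOfWarParams",
    "MotorState",
    "CargoMechanics",
    "binding_rate",
    "unbinding_rate",
    "motor_velocity",
    "cargo_mechanics",
    "default_params",
]


@dataclass(frozen=True)
class MotorTeamParams:
    """Constants of a single motor of one team.

    Parameters
    ----------
    stall_force_pN
        Load at which the motor velocity reaches zero.
    detachment_force_pN
        Force scale of the exponential load dependence of unbinding.
    binding_rate_per_s
        Force-independent attachment rate ``pi_0`` of an unbound motor.
    unbinding_rate_per_s
        Zero-load detachment rate ``epsilon_0``.
    forward_speed_um_s
        Unloaded speed ``v_F`` toward the team's own travel direction.
    backslip_speed_um_s
        Slow speed scale ``v_B`` of the superstall branch.
    """

    stall_force_pN: float
    detachment_force_pN: float
    binding_rate_per_s: float
    unbinding_rate_per_s: float
    forward_speed_um_s: float
    backslip_speed_um_s: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        if self.backslip_speed_um_s >= self.forward_speed_um_s:
            raise ValueError(
                "backslip_speed_um_s must be smaller than forward_speed_um_s"
            )


@dataclass(frozen=True)
class TugOfWarParams:
    """Full parameter set of the two-team tug-of-war.

    ``forward`` drives the cargo apexward (+x), ``backward`` toward the
    pollen grain (-x).  ``n_motors`` is the size of the single shared pool;
    every unbound motor may join either team.
    """

    forward: MotorTeamParams
    backward: MotorTeamParams
    n_motors: int

    def __post_init__(self) -> None:
        if int(self.n_motors) != self.n_motors or self.n_motors < 1:
            raise ValueError(f"n_motors must be an integer >= 1, got {self.n_motors!r}")

    def with_n_motors(self, n_motors: int) -> "TugOfWarParams":
        return TugOfWarParams(self.forward, self.backward, n_motors)

    def to_dict(self) -> dict:
        d = {}
        for team, prefix in ((self.forward, "forward_"), (self.backward, "backward_")):
            for key, value in asdict(team).items():
                d[prefix + key] = value
        d["n_motors"] = self.n_motors
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TugOfWarParams":
        fields = (
            "stall_force_pN",
            "detachment_force_pN",
            "binding_rate_per_s",
            "unbinding_rate_per_s",
            "forward_speed_um_s",
            "backslip_speed_um_s",
        )
        teams = {}
        for prefix in ("forward_", "backward_"):
            try:
                teams[prefix] = MotorTeamParams(**{f: float(d[prefix + f]) for f in fields})
            except KeyError as exc:
                raise KeyError(f"missing parameter key {prefix}{exc.args[0]}") from None
        return cls(teams["forward_"], teams["backward_"], int(d["n_motors"]))


def default_params() -> TugOfWarParams:
    """The Methods parameter set: 70 motors, equal 3 pN stall and 10 pN
    detachment forces, asymmetric kinetics and speeds favouring forward
    transport."""
    return TugOfWarParams(
        forward=MotorTeamParams(
            stall_force_pN=3.0,
            detachment_force_pN=10.0,
            binding_rate_per_s=0.7,
            unbinding_rate_per_s=1.7,
            forward_speed_um_s=0.08,
            backslip_speed_um_s=0.008,
        ),
        backward=MotorTeamParams(
            stall_force_pN=3.0,
            detachment_force_pN=10.0,
            binding_rate_per_s=0.6,
            unbinding_rate_per_s=1.6,
            forward_speed_um_s=0.01,
            backslip_speed_um_s=0.001,
        ),
        n_motors=70,
    )


class MotorState(NamedTuple):
    """Bound-motor counts ``(n_plus, n_minus)`` against the shared pool."""

    n_plus: int
    n_minus: int


@dataclass(frozen=True)
class CargoMechanics:
    """Instantaneous cargo force, signed velocity and dominance class.

    ``dominance`` is one of ``"forward"``, ``"backward"``, ``"balanced"``,
    ``"unbound"``.  ``velocity_um_s`` is signed in the cargo frame
    (+ = apexward); ``force_pN`` is the magnitude of the tension each team
    shares.
    """

    force_pN: float
    velocity_um_s: float
    dominance: str


def binding_rate(team: MotorTeamParams, force_pN: float = 0.0) -> float:
    """Attachment rate of one unbound motor; independent of load."""
    return team.binding_rate_per_s


def unbinding_rate(force_pN: float, team: MotorTeamParams) -> float:
    """Detachment rate ``epsilon_0 * exp(|F| / F_d)`` of one bound motor."""
    if not math.isfinite(force_pN):
        raise ValueError(f"force must be finite, got {force_pN!r}")
    return team.unbinding_rate_per_s * math.exp(abs(force_pN) / team.detachment_force_pN)


def motor_velocity(force_pN: float, team: MotorTeamParams) -> float:
    """Single-motor velocity under opposing load ``F >= 0``.

    Linear force-velocity relation in the motor's own travel direction:
    ``v_F (1 - F/F_s)`` up to stall, continuing as the shallow backslip
    branch ``v_B (1 - F/F_s)`` (negative) above stall.  The caller owns the
    cargo-frame sign convention.
    """
    if not math.isfinite(force_pN) or force_pN < 0:
        raise ValueError(f"load must be finite and >= 0, got {force_pN!r}")
    reduced = 1.0 - force_pN / team.stall_force_pN
    if force_pN <= team.stall_force_pN:
        return team.forward_speed_um_s * reduced
    return team.backslip_speed_um_s * reduced


def cargo_mechanics(state: MotorState, params: TugOfWarParams) -> CargoMechanics:
    """Force balance of the two bound teams.

    The dominant team (larger total stall load ``n * F_s``) advances below
    stall while dragging the other team backward along its superstall
    branch.  The cargo force follows the interpolation
    ``F_c = lam * n_plus * F_s_plus + (1 - lam) * n_minus * F_s_minus`` and the
    cargo velocity the ratio of the stall-load excess to the summed
    compliance ``n F_s / v`` of the winning (forward-branch) and losing
    (backslip-branch) teams.  Both satisfy
    ``v_c = v_plus(F_c/n_plus) = -v_minus(F_c/n_minus)``.

    Degenerate cases are closed-form: with no bound motor the cargo rests;
    a lone team runs unloaded at its own ``v_F``; equal stall loads stall
    both teams (``v_c = 0``, ``F_c = n_plus * F_s_plus``).
    """
    n_plus, n_minus = state
    if n_plus < 0 or n_minus < 0 or n_plus + n_minus > params.n_motors:
        raise ValueError(f"invalid motor state {state!r} for N={params.n_motors}")
    fwd, bwd = params.forward, params.backward
    if n_plus == 0 and n_minus == 0:
        return CargoMechanics(0.0, 0.0, "unbound")
    if n_minus == 0:
        return CargoMechanics(0.0, fwd.forward_speed_um_s, "forward")
    if n_plus == 0:
        return CargoMechanics(0.0, -bwd.forward_speed_um_s, "backward")

    a = n_plus * fwd.stall_force_pN   # total stall load, forward team
    b = n_minus * bwd.stall_force_pN  # total stall load, backward team
    if a == b:
        return CargoMechanics(a, 0.0, "balanced")
    if a > b:
        lam = 1.0 / (1.0 + (a * bwd.backslip_speed_um_s) / (b * fwd.forward_speed_um_s))
        v_c = (a - b) / (a / fwd.forward_speed_um_s + b / bwd.backslip_speed_um_s)
        dominance = "forward"
    else:
        lam = 1.0 / (1.0 + (a * bwd.forward_speed_um_s) / (b * fwd.backslip_speed_um_s))
        v_c = (a - b) / (a / fwd.backslip_speed_um_s + b / bwd.forward_speed_um_s)
        dominance = "backward"
    f_c = lam * a + (1.0 - lam) * b
    return CargoMechanics(f_c, v_c, dominance)
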