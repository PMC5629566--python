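"""Result containers shared by the design methods."""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import KnockoutDesign


@dataclass
class DesignResult:
    """A knockout design together with its predicted or guaranteed target flux.

    ``objective`` is the optimistic (cooperative) maximum target flux for
    optknock/room, and the guaranteed worst-case target flux for the
    pessimistic methods (which also carry the tolerance ``epsilon``).
    """

    design: KnockoutDesign
    objective: float
    method: str  # optknock | room | p_room | p_optknock | oracle-*
    epsilon: float | None = None
    status: str = "optimal"
    solver_stats: dict = field(default_factory=dict)

    @property
    def knocked(self) -> list[str]:
        return sorted(self.design.knocked)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "knocked": self.knocked,
            "budget": self.design.budget,
            "objective": self.objective,
            "epsilon": self.epsilon,
            "status": self.status,
            "solver_stats": self.solver_stats,
        }
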