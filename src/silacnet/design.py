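"""Sample design: pulldown conditions x replicates, with a beads-only control."""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_CONDITIONS: tuple[str, ...] = (
    "H3_1-20_unmod",
    "H3K9me3",
    "H3S10ph",
    "H3K9me3S10ph",
    "H3_18-38_unmod",
    "H3K27me3",
    "H3S28ph",
    "H3K27me3S28ph",
    "beads",
)


@dataclass(frozen=True)
class SampleDesign:
    """Ordered pulldown conditions with a replicate count and a negative control.

    Samples are ordered condition-major: all replicates of the first condition,
    then all replicates of the second, and so on. Sample names are
    ``"<condition>_rep<k>"`` with k starting at 1.
    """

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates: int = 2
    beads_condition: str = "beads"

    def __post_init__(self) -> None:
        conditions = tuple(self.conditions)
        object.__setattr__(self, "conditions", conditions)
        if len(set(conditions)) != len(conditions):
            raise ValueError("condition names must be unique")
        if not conditions:
            raise ValueError("at least one condition is required")
        if self.beads_condition not in conditions:
            raise ValueError(
                f"beads_condition {self.beads_condition!r} is not among conditions"
            )
        if self.replicates < 1:
            raise ValueError("replicates must be a positive integer")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_samples(self) -> int:
        return len(self.conditions) * self.replicates

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{condition}_rep{rep}"
            for condition in self.conditions
            for rep in range(1, self.replicates + 1)
        ]

    @property
    def specific_conditions(self) -> tuple[str, ...]:
        """Conditions excluding the beads-only control."""
        return tuple(c for c in self.conditions if c != self.beads_condition)

    def samples_of(self, condition: str) -> list[str]:
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        return [f"{condition}_rep{rep}" for rep in range(1, self.replicates + 1)]

    def condition_of(self, sample_name: str) -> str:
        condition, sep, rep = sample_name.rpartition("_rep")
        if not sep or condition not in self.conditions:
            raise KeyError(f"sample name {sample_name!r} does not match the design")
        return condition

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "replicates": self.replicates,
            "beads_condition": self.beads_condition,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SampleDesign":
        return cls(
            conditions=tuple(payload.get("conditions", DEFAULT_CONDITIONS)),
            replicates=int(payload.get("replicates", 2)),
            beads_condition=payload.get("beads_condition", "beads"),
        )
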