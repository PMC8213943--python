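"""Experiment design for the VOT identification / AX-discrimination tasks.

Each stimulus continuum spans voice onset times from -50 ms to +50 ms in
10-ms steps (11 stimuli).  The AX discrimination test uses "different"
pairs separated by 20-ms VOT, presented in both orders, plus one "same"
pair per stimulus.  Discrimination scores are later indexed by the pair
*center* (the midpoint VOT of a different pair), giving nine centers from
-40 to +40 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CONTINUA = ("ba_pa", "de_te", "di_ti")

VOT_LEVELS_MS: tuple[int, ...] = tuple(range(-50, 51, 10))
PAIR_SEPARATION_MS = 20
PAIR_CENTERS_MS: tuple[int, ...] = tuple(range(-40, 41, 10))

#: voiced / voiceless endpoint category per continuum (negative VOT = voiced)
VOICED_LABEL = "voiced"
VOICELESS_LABEL = "voiceless"


class DesignError(ValueError):
    """Raised for an invalid continuum label or malformed design request."""


@dataclass(frozen=True)
class ContinuumDesign:
    """Full trial schedule for one VOT continuum.

    Attributes
    ----------
    label:
        One of ``ba_pa``, ``de_te``, ``di_ti``.
    vot_levels_ms:
        The 11 stimulus VOT values, strictly increasing, -50 ... +50 ms.
    ident_reps:
        Identification repetitions per stimulus (8 -> 88 trials).
    pair_reps:
        Repetitions per AX pair (8 -> (18 + 11) * 8 = 232 trials).
    """

    label: str
    vot_levels_ms: tuple[int, ...] = VOT_LEVELS_MS
    ident_reps: int = 8
    pair_reps: int = 8
    pair_separation_ms: int = PAIR_SEPARATION_MS
    different_pairs: tuple[tuple[int, int], ...] = field(init=False)
    same_pairs: tuple[tuple[int, int], ...] = field(init=False)
    pair_centers_ms: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.label not in CONTINUA:
            raise DesignError(
                f"unknown continuum {self.label!r}; expected one of {CONTINUA}"
            )
        levels = self.vot_levels_ms
        if len(levels) != 11 or any(b <= a for a, b in zip(levels, levels[1:])):
            raise DesignError("vot_levels_ms must be 11 strictly increasing values")
        step = levels[1] - levels[0]
        if self.pair_separation_ms != 2 * step:
            raise DesignError("pair separation must equal two grid steps")
        sep = self.pair_separation_ms
        combos = [(a, a + sep) for a in levels if a + sep <= levels[-1]]
        ordered = [p for ab in combos for p in (ab, ab[::-1])]
        object.__setattr__(self, "different_pairs", tuple(ordered))
        object.__setattr__(self, "same_pairs", tuple((v, v) for v in levels))
        object.__setattr__(
            self, "pair_centers_ms", tuple((a + b) // 2 for a, b in combos)
        )

    @property
    def n_ident_trials(self) -> int:
        return len(self.vot_levels_ms) * self.ident_reps

    @property
    def n_discrim_trials(self) -> int:
        return (len(self.different_pairs) + len(self.same_pairs)) * self.pair_reps

    def endpoint_truth(self) -> dict[int, str]:
        """Correct category label at the two continuum endpoints."""
        return {
            self.vot_levels_ms[0]: VOICED_LABEL,
            self.vot_levels_ms[-1]: VOICELESS_LABEL,
        }


def enumerate_design(continuum_label: str, *, ident_reps: int = 8,
                     pair_reps: int = 8) -> ContinuumDesign:
    """Build the trial schedule for one continuum.

    Raises
    ------
    DesignError
        If ``continuum_label`` is not a known continuum.
    """
    return ContinuumDesign(label=continuum_label, ident_reps=ident_reps,
                           pair_reps=pair_reps)


def centers_for_same_pair(vot_ms: int) -> tuple[int, ...]:
    """Pair centers to which the same pair (v, v) contributes.

    A same pair at VOT v is pooled with the different pairs that contain
    stimulus v, i.e. the centers v - 10 and v + 10 that exist on the grid.
    Interior stimuli therefore contribute to two centers, the endpoint
    stimuli to one.
    """
    return tuple(c for c in (vot_ms - 10, vot_ms + 10) if c in PAIR_CENTERS_MS)
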