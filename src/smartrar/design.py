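"""SMART trial designs, embedded regimes, feasible sets, and consistency indicators.

A SMART (sequential multiple assignment randomized trial) randomizes each
subject at ``K`` decision points; the options available at stage ``k`` may
depend on earlier treatment and interim response.  The finitely many regimes
implied by the randomization structure are the *embedded regimes*: for the
two-stage designs handled concretely here, triples ``(a, b, c)`` meaning
"give ``a`` initially; on response give ``b``, on nonresponse give ``c``".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field


class DesignError(ValueError):
    """Raised for ill-formed designs or invalid history keys."""


@dataclass(frozen=True)
class EmbeddedRegime:
    """One embedded regime of a two-stage SMART.

    Attributes
    ----------
    id : int
        1-based regime index ``j``.
    stage1 : int
        Initial treatment ``a``.
    responder : int
        Stage-2 treatment ``b`` for responders.
    nonresponder : int
        Stage-2 treatment ``c`` for nonresponders.
    """

    id: int
    stage1: int
    responder: int
    nonresponder: int

    def action(self, stage: int, response: int | None = None) -> int:
        """Recommended treatment at ``stage`` (1-based) given response status."""
        if stage == 1:
            return self.stage1
        if stage == 2:
            if response not in (0, 1):
                raise DesignError("stage-2 recommendation requires response in {0,1}")
            return self.responder if response else self.nonresponder
        raise DesignError(f"stage {stage} outside this two-stage regime")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.stage1, self.responder, self.nonresponder)


@dataclass
class SMARTDesign:
    """A two-stage SMART design with response-dependent stage-2 feasible sets.

    Parameters
    ----------
    treatment_sets : list of sets
        ``treatment_sets[k-1]`` is the full option set at stage ``k``.
    feasible_stage2 : dict
        Maps ``(a1, response)`` to the feasible subset of stage-2 options.
    stage_gap_weeks : int
        Weeks between consecutive assignments, and between the final
        assignment and outcome ascertainment.
    """

    treatment_sets: list[set[int]]
    feasible_stage2: dict[tuple[int, int], frozenset[int]]
    stage_gap_weeks: int = 6
    embedded_regimes: list[EmbeddedRegime] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage_gap_weeks <= 0:
            raise DesignError("stage_gap_weeks must be positive")
        if len(self.treatment_sets) != 2:
            raise DesignError("this design class is two-stage (K=2)")
        if not self.treatment_sets[0]:
            raise DesignError("empty stage-1 treatment set")
        self.feasible_stage2 = {
            k: frozenset(v) for k, v in self.feasible_stage2.items()
        }
        for key, opts in self.feasible_stage2.items():
            if not opts:
                raise DesignError(f"empty feasible set for history {key}")
            if not opts <= self.treatment_sets[1]:
                raise DesignError(f"feasible set {opts} not within stage-2 options")
        if not self.embedded_regimes:
            self.embedded_regimes = enumerate_embedded_regimes(self)
        for reg in self.embedded_regimes:
            for resp in (0, 1):
                if reg.action(2, resp) not in self.feasible_set(2, reg.stage1, resp):
                    raise DesignError(f"regime {reg.id} recommends infeasible option")

    @property
    def K(self) -> int:
        return len(self.treatment_sets)

    @property
    def n_regimes(self) -> int:
        return len(self.embedded_regimes)

    def feasible_set(
        self, stage: int, a1: int | None = None, response: int | None = None
    ) -> frozenset[int]:
        """Feasible options at ``stage`` for the history ``(a1, response)``."""
        if stage == 1:
            return frozenset(self.treatment_sets[0])
        if stage == 2:
            key = (a1, response)
            if key not in self.feasible_stage2:
                raise DesignError(f"unknown stage-2 history {key}")
            return self.feasible_stage2[key]
        raise DesignError(f"stage {stage} outside design")

    def stage1_family(self, a1: int) -> list[int]:
        """0-based indices of embedded regimes whose initial treatment is ``a1``."""
        return [i for i, r in enumerate(self.embedded_regimes) if r.stage1 == a1]


def enumerate_embedded_regimes(design: SMARTDesign) -> list[EmbeddedRegime]:
    """All embedded regimes of a two-stage design.

    Regimes are ordered by stage-1 treatment, then responder option, with the
    nonresponder options traversed boustrophedon (ascending under the first
    responder option, descending under the next, and so on).  For the
    cancer-pain design this reproduces the published numbering
    (0,0,1), (0,0,2), (0,1,2), (0,1,1), (1,3,4), (1,3,5), (1,4,5), (1,4,4).
    """
    regimes: list[EmbeddedRegime] = []
    j = 0
    for a1 in sorted(design.treatment_sets[0]):
        resp_opts = sorted(design.feasible_set(2, a1, 1))
        nonresp_opts = sorted(design.feasible_set(2, a1, 0))
        for i, b in enumerate(resp_opts):
            cs = nonresp_opts if i % 2 == 0 else nonresp_opts[::-1]
            for c in cs:
                j += 1
                regimes.append(EmbeddedRegime(id=j, stage1=a1, responder=b, nonresponder=c))
    return regimes


def cancer_pain_design() -> SMARTDesign:
    """The two-stage behavioral cancer-pain-management SMART.

    Stage 1 compares a brief (0) vs. full (1) pain coping skills training
    program.  Stage-2 options depend on the initial program and on whether
    the subject responded (a 30% reduction in pain score): nonresponders to
    the brief program may receive maintenance (1) or the full program (2);
    responders may stop (0) or receive maintenance (1); and analogously for
    the full program with options 3 (stop), 4 (maintenance), 5 (augmented).
    """
    return SMARTDesign(
        treatment_sets=[{0, 1}, {0, 1, 2, 3, 4, 5}],
        feasible_stage2={
            (0, 1): frozenset({0, 1}),
            (0, 0): frozenset({1, 2}),
            (1, 1): frozenset({3, 4}),
            (1, 0): frozenset({4, 5}),
        },
    )


def regime_consistency(
    a1: int,
    response: int | None,
    a2: int | None,
    regime: EmbeddedRegime,
    through_stage: int = 2,
) -> int:
    """Indicator that realized treatments agree with ``regime`` through a stage.

    ``through_stage=1`` checks only the initial assignment (the partial
    indicator C̄₁); ``through_stage=2`` additionally requires the stage-2
    treatment to match the regime's recommendation for the realized response
    status (the full indicator C).
    """
    if through_stage not in (1, 2):
        raise DesignError("through_stage must be 1 or 2")
    if a1 != regime.stage1:
        return 0
    if through_stage == 1:
        return 1
    if response is None or a2 is None:
        raise DesignError("record has not reached stage 2")
    return int(a2 == regime.action(2, response))
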