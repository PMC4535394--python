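import pytest

from simon2stage import SimonDesign, TrialOutcome


@pytest.fixture(scope="session")
def gi_design() -> SimonDesign:
    """The hepatobiliary-cancer trial design: optimal for 0.15 vs 0.30
    at one-sided level 0.10 with 80% power."""
    return SimonDesign(r1=3, n1=19, rt=8, nt=39, pi0=0.15, pi1=0.30,
                       alpha=0.10, beta=0.20)


@pytest.fixture(scope="session")
def gi_outcome() -> TrialOutcome:
    """The observed trial: 8/19 at stage 1, then 4/6 in a second stage cut
    short by funding (planned n2 was 20)."""
    return TrialOutcome(m=2, x1=8, x2=4, n2_actual=6)


@pytest.fixture(scope="session")
def tiny_design() -> SimonDesign:
    """Smallest nontrivial design: stop if 0/1, else add one patient.

    Support has exactly three paths: (1,0), (2,1), (2,2)."""
    return SimonDesign(r1=0, n1=1, rt=1, nt=2)


@pytest.fixture(scope="session")
def small_designs() -> list[SimonDesign]:
    """A few small designs for exhaustive-enumeration checks."""
    return [
        SimonDesign(r1=0, n1=1, rt=1, nt=2),
        SimonDesign(r1=1, n1=4, rt=3, nt=8),
        SimonDesign(r1=2, n1=7, rt=5, nt=12),
    ]


# The twelve published 90% designs with the nominal (alpha, beta) each
# actually attains (verified by exact enumeration of the two-stage
# rejection probability).
PUBLISHED_DESIGNS = [
    # (r1, n1, rt, nt), (pi0, pi1), alpha, beta
    ((3, 17, 10, 37), (0.2, 0.4), 0.10, 0.10),
    ((7, 22, 17, 46), (0.3, 0.5), 0.10, 0.10),
    ((7, 18, 22, 46), (0.4, 0.6), 0.10, 0.10),
    ((11, 21, 26, 45), (0.5, 0.7), 0.10, 0.10),
    ((3, 13, 12, 43), (0.2, 0.4), 0.05, 0.20),
    ((5, 15, 18, 46), (0.3, 0.5), 0.05, 0.20),
    ((7, 16, 23, 46), (0.4, 0.6), 0.05, 0.20),
    ((8, 15, 26, 43), (0.5, 0.7), 0.05, 0.20),
    ((4, 19, 15, 54), (0.2, 0.4), 0.05, 0.10),
    ((8, 24, 24, 63), (0.3, 0.5), 0.05, 0.10),
    ((11, 25, 32, 66), (0.4, 0.6), 0.05, 0.10),
    ((13, 24, 36, 61), (0.5, 0.7), 0.05, 0.10),
]
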