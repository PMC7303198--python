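"""Multi-feature oddball design: stimuli, sequences, identity map, validation.

A condition block presents one pseudoword as the frequent standard (SD) and
two rare deviants: a formal deviant (FD, the consonant cluster -ts-/-tk- is
exchanged, i.e. phonotactic probability flips) and a temporal deviant (TD,
the stressed syllable flips).  Each of the four stimuli in the 2x2 crossing
of phonotactic probability (HPP/LPP) and syllable stress (SylStr1/SylStr2)
serves as the standard of its own condition, so every deviant has an
identical-stimulus standard in another condition -- the basis of the
identical-stimulus difference waves downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence as TypingSequence

import numpy as np
import pandas as pd

PHONPROB_LEVELS = ("HPP", "LPP")
SYLSTR_LEVELS = ("SylStr1", "SylStr2")
ROLES = ("SD", "FD", "TD")

#: Default per-role trial tallies of one condition block set.
DEFAULT_COUNTS = {"SD": 1332, "FD": 144, "TD": 144}
DEFAULT_SEP_RANGE = (1, 8)
DEFAULT_TRIAL_DURATION_MS = 1200
DEFAULT_BLOCK_SIZE = 270
DEFAULT_N_TOKENS = 3


class DesignError(ValueError):
    """Raised when a requested oddball design is infeasible or malformed."""


@dataclass(frozen=True)
class StimulusSpec:
    """One pseudoword stimulus.

    Parameters
    ----------
    id : str
        Label; capitalization marks the stressed syllable (e.g. ``NOTsal``).
    phonprob : {"HPP", "LPP"}
        Phonotactic probability of the medial cluster (-ts- high, -tk- low).
    sylstr : {"SylStr1", "SylStr2"}
        Stressed syllable (first or second).
    duration_ms : float
        Stimulus duration.
    deviation_onset_formal_ms : float
        Time of the /t/-onset (where formal deviants first differ from the
        standard), relative to stimulus onset.
    deviation_onset_temporal_ms : float
        Time where temporal deviants first differ (stimulus onset).
    """

    id: str
    phonprob: str
    sylstr: str
    duration_ms: float = 600.0
    deviation_onset_formal_ms: float = 250.0
    deviation_onset_temporal_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.phonprob not in PHONPROB_LEVELS:
            raise DesignError(f"phonprob must be one of {PHONPROB_LEVELS}, got {self.phonprob!r}")
        if self.sylstr not in SYLSTR_LEVELS:
            raise DesignError(f"sylstr must be one of {SYLSTR_LEVELS}, got {self.sylstr!r}")
        if self.duration_ms <= 0:
            raise DesignError("duration_ms must be positive")
        for name in ("deviation_onset_formal_ms", "deviation_onset_temporal_ms"):
            v = getattr(self, name)
            if not (0 <= v < self.duration_ms):
                raise DesignError(f"{name}={v} outside [0, duration)")

    def deviation_onset_ms(self, role: str) -> float:
        """Deviation onset for a deviant role (FD: /t/-onset, TD: stimulus onset)."""
        if role == "FD":
            return self.deviation_onset_formal_ms
        if role == "TD":
            return self.deviation_onset_temporal_ms
        raise DesignError(f"no deviation onset for role {role!r}")


def default_stimuli() -> list[StimulusSpec]:
    """The notsal quadruplet: full 2x2 crossing of phonprob and stress."""
    return [
        StimulusSpec("NOTsal", "HPP", "SylStr1"),
        StimulusSpec("NOTkal", "LPP", "SylStr1"),
        StimulusSpec("notSAL", "HPP", "SylStr2"),
        StimulusSpec("notKAL", "LPP", "SylStr2"),
    ]


@dataclass(frozen=True)
class TrialEvent:
    """One trial in an oddball block: a stimulus presented in a role."""

    index: int
    stimulus: str
    role: str
    condition: str
    onset_ms: float
    token: int = 1


@dataclass
class OddballSequence:
    """Ordered trial events of one condition block set.

    ``condition`` is named after its standard stimulus.  ``block_size`` is
    bookkeeping metadata (trials per presentation block); analysis pools
    across blocks.
    """

    condition: str
    trials: list[TrialEvent]
    trial_duration_ms: float = DEFAULT_TRIAL_DURATION_MS
    seed: int | None = None
    block_size: int | None = DEFAULT_BLOCK_SIZE

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def counts(self) -> dict[str, int]:
        out = {r: 0 for r in ROLES}
        for t in self.trials:
            out[t.role] = out.get(t.role, 0) + 1
        return out

    @property
    def roles(self) -> np.ndarray:
        return np.array([t.role for t in self.trials])

    def to_frame(self) -> pd.DataFrame:
        """Event table (index, onset_ms, stimulus, role, condition, token)."""
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "onset_ms": [t.onset_ms for t in self.trials],
                "stimulus": [t.stimulus for t in self.trials],
                "role": [t.role for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "token": [t.token for t in self.trials],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def separation_histogram(seq: OddballSequence, per_role: bool = True) -> dict:
    """Count, for each deviant, the number of standards since the previous
    deviant (the block start counts as a boundary)."""
    seps: dict[str, list[int]] = {"FD": [], "TD": []}
    run = 0
    for t in seq.trials:
        if t.role == "SD":
            run += 1
        else:
            seps.setdefault(t.role, []).append(run)
            run = 0
    if per_role:
        return {r: np.bincount(v, minlength=1) if v else np.array([0]) for r, v in seps.items()}
    allv = [s for v in seps.values() for s in v]
    return {"all": np.bincount(allv, minlength=1) if allv else np.array([0])}


def _balanced_gaps(count: int, sep_range: tuple[int, int], rng: np.random.Generator) -> list[int]:
    """Allocate `count` inter-deviant separations as equally as possible over
    sep_range (144 deviants over 1..8 -> exactly 18 each); any remainder goes
    to the smallest separations to keep the standard budget feasible."""
    lo, hi = sep_range
    bins = list(range(lo, hi + 1))
    base, rem = divmod(count, len(bins))
    gaps = []
    for b in bins:
        gaps.extend([b] * base)
    for b in bins[:rem]:
        gaps.append(b)
    rng.shuffle(gaps)
    return gaps


def generate_condition_sequence(
    standard: StimulusSpec,
    deviants: TypingSequence[StimulusSpec],
    counts: dict[str, int] | None = None,
    sep_range: tuple[int, int] = DEFAULT_SEP_RANGE,
    trial_duration_ms: float = DEFAULT_TRIAL_DURATION_MS,
    seed: int = 0,
    balanced: bool = True,
    n_tokens: int = DEFAULT_N_TOKENS,
    block_size: int | None = DEFAULT_BLOCK_SIZE,
    max_tries: int = 1000,
) -> OddballSequence:
    """Generate a pseudorandom oddball block for one condition.

    Standards (the condition's standard stimulus) are frequent; formal and
    temporal deviants are interleaved, each preceded by 1-8 standards
    (``sep_range``) counted since the previous deviant of any type.  With
    ``balanced=True`` each deviant type's separations are allocated equally
    over ``sep_range`` in random order; with ``balanced=False`` separations
    are drawn uniformly.  Leftover standards are appended after the last
    deviant.  Reproducible under ``seed``.

    Raises
    ------
    DesignError
        If ``sep_range`` starts below 1 or the requested tallies cannot be
        met (sum of separations exceeds the standard count).
    """
    counts = dict(DEFAULT_COUNTS if counts is None else counts)
    lo, hi = sep_range
    if lo < 1:
        raise DesignError(f"sep_range minimum must be >= 1, got {lo}")
    if hi < lo:
        raise DesignError(f"sep_range max < min: {sep_range}")
    n_sd = counts.get("SD", 0)
    dev_counts = {r: c for r, c in counts.items() if r != "SD" and c > 0}
    role_to_stim = {}
    for d in deviants:
        pp_diff = d.phonprob != standard.phonprob
        ss_diff = d.sylstr != standard.sylstr
        if pp_diff == ss_diff:
            raise DesignError(
                f"deviant {d.id} must differ from standard {standard.id} in exactly one feature"
            )
        role_to_stim["FD" if pp_diff else "TD"] = d
    for r in dev_counts:
        if r not in role_to_stim:
            raise DesignError(f"count requested for role {r} but no matching deviant stimulus")
    n_dev_total = sum(dev_counts.values())
    if n_dev_total * lo > n_sd:
        raise DesignError(
            f"infeasible design: {n_dev_total} deviants need at least "
            f"{n_dev_total * lo} separating standards, only {n_sd} available"
        )

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        if balanced:
            gaps_by_role = {r: _balanced_gaps(c, sep_range, rng) for r, c in dev_counts.items()}
        else:
            gaps_by_role = {
                r: list(rng.integers(lo, hi + 1, size=c)) for r, c in dev_counts.items()
            }
        total_gap = sum(sum(g) for g in gaps_by_role.values())
        if total_gap <= n_sd:
            break
        if balanced:  # the balanced allocation is deterministic: no point retrying
            raise DesignError(
                f"infeasible design: balanced separations need {total_gap} "
                f"standards, only {n_sd} available"
            )
    else:
        raise DesignError(
            "could not draw separations fitting the standard budget "
            f"within {max_tries} tries; reduce deviant counts or sep_range"
        )

    # Interleave deviant types in random order; consume each type's gap list.
    dev_order = [r for r, c in dev_counts.items() for _ in range(c)]
    rng.shuffle(dev_order)
    cursors = {r: 0 for r in dev_counts}
    events: list[tuple[str, StimulusSpec]] = []
    used_sd = 0
    for r in dev_order:
        g = gaps_by_role[r][cursors[r]]
        cursors[r] += 1
        events.extend([("SD", standard)] * g)
        used_sd += g
        events.append((r, role_to_stim[r]))
    events.extend([("SD", standard)] * (n_sd - used_sd))

    tokens = rng.integers(1, n_tokens + 1, size=len(events))
    trials = [
        TrialEvent(
            index=i,
            stimulus=stim.id,
            role=role,
            condition=standard.id,
            onset_ms=i * trial_duration_ms,
            token=int(tokens[i]),
        )
        for i, (role, stim) in enumerate(events)
    ]
    return OddballSequence(
        condition=standard.id,
        trials=trials,
        trial_duration_ms=trial_duration_ms,
        seed=seed,
        block_size=block_size,
    )


def deviants_for(standard: StimulusSpec, stimuli: TypingSequence[StimulusSpec]) -> dict[str, StimulusSpec]:
    """The formal (phonprob flipped) and temporal (stress flipped) deviants
    of a standard, looked up in the full stimulus crossing."""
    _check_crossing(stimuli)
    by_attr = {(s.phonprob, s.sylstr): s for s in stimuli}
    other_pp = PHONPROB_LEVELS[1 - PHONPROB_LEVELS.index(standard.phonprob)]
    other_ss = SYLSTR_LEVELS[1 - SYLSTR_LEVELS.index(standard.sylstr)]
    return {
        "FD": by_attr[(other_pp, standard.sylstr)],
        "TD": by_attr[(standard.phonprob, other_ss)],
    }


def _check_crossing(stimuli: TypingSequence[StimulusSpec]) -> None:
    cells = {(s.phonprob, s.sylstr) for s in stimuli}
    if len(stimuli) != 4 or len(cells) != 4:
        raise DesignError(
            "stimuli must form a full 2x2 phonprob x sylstr crossing "
            f"(got {len(stimuli)} stimuli spanning {len(cells)} cells)"
        )


def build_identity_map(stimuli: TypingSequence[StimulusSpec]) -> dict[tuple[str, str], str]:
    """Map each (condition, deviant role) to the condition in which the
    identical stimulus is the standard.

    Conditions are named after their standard stimulus, so the mapped value
    is simply the deviant stimulus id; the map makes the cross-condition
    structure explicit and is validated to cover all 8 deviant cells.
    """
    _check_crossing(stimuli)
    out: dict[tuple[str, str], str] = {}
    for s in stimuli:
        devs = deviants_for(s, stimuli)
        out[(s.id, "FD")] = devs["FD"].id
        out[(s.id, "TD")] = devs["TD"].id
    assert len(out) == 8
    for (cond, role), mapped in out.items():
        assert mapped != cond
    return out


@dataclass
class CheckResult:
    name: str
    passed: bool
    first_offending_index: int | None = None
    detail: str = ""


def validate_sequence(
    seq: OddballSequence,
    expected_counts: dict[str, int] | None = None,
    sep_range: tuple[int, int] = DEFAULT_SEP_RANGE,
) -> list[CheckResult]:
    """Report-only validation of a generated sequence against the design
    invariants (tallies, separation range, leading standard, onset grid,
    role/stimulus consistency, block partition)."""
    checks: list[CheckResult] = []

    if expected_counts is not None:
        got = seq.counts
        bad = {r: (got.get(r, 0), c) for r, c in expected_counts.items() if got.get(r, 0) != c}
        checks.append(
            CheckResult("tallies", not bad, None, f"mismatches: {bad}" if bad else "")
        )

    lo, hi = sep_range
    run = 0
    sep_ok = True
    sep_idx: int | None = None
    for t in seq.trials:
        if t.role == "SD":
            run += 1
        else:
            if not (lo <= run <= hi):
                sep_ok, sep_idx = False, t.index
                break
            run = 0
    checks.append(CheckResult("separations_in_range", sep_ok, sep_idx))

    starts_sd = len(seq) > 0 and seq.trials[0].role == "SD"
    checks.append(CheckResult("starts_with_standard", starts_sd, None if starts_sd else 0))

    onset_idx = None
    for t in seq.trials:
        if abs(t.onset_ms - t.index * seq.trial_duration_ms) > 1e-9:
            onset_idx = t.index
            break
    checks.append(CheckResult("onsets_on_trial_grid", onset_idx is None, onset_idx))

    role_idx = None
    for t in seq.trials:
        if t.role == "SD" and t.stimulus != seq.condition:
            role_idx = t.index
            break
        if t.role in ("FD", "TD") and t.stimulus == seq.condition:
            role_idx = t.index
            break
    checks.append(CheckResult("roles_match_stimuli", role_idx is None, role_idx))

    if seq.block_size:
        ok = len(seq) % seq.block_size == 0
        checks.append(
            CheckResult(
                "block_partition",
                ok,
                None,
                f"{len(seq)} trials not divisible by block size {seq.block_size}" if not ok else "",
            )
        )
    return checks


# ---------------------------------------------------------------------------
# Stimulus-selection frequency table: summed INL (Instituut voor de
# Nederlandse Taal) corpus word frequencies of the target phoneme clusters
# and stress patterns, carried as fixed design metadata.
# ---------------------------------------------------------------------------

#: Summed corpus word frequencies by scope.  "AllBiSyl" = all bisyllabic
#: words; "CVCCVC" = bisyllabic words with CVCCVC structure.  Cluster columns
#: count words containing -ts- (high phonotactic probability) or -tk- (low);
#: stress columns count words with first or second syllable stress.
FREQUENCY_TABLE = pd.DataFrame(
    {
        "ts_freq": [94061, 12270],
        "tk_freq": [7787, np.nan],
        "sylstr1_freq": [7633058, 2927941],
        "sylstr2_freq": [1926345, 188171],
    },
    index=pd.Index(["AllBiSyl", "CVCCVC"], name="scope"),
)


def stress_ratio(scope: str = "AllBiSyl") -> float:
    """First- over second-syllable-stress frequency ratio for a scope."""
    row = FREQUENCY_TABLE.loc[scope]
    return float(row["sylstr1_freq"] / row["sylstr2_freq"])


def cluster_ratio(scope: str = "AllBiSyl") -> float:
    """-ts- over -tk- frequency ratio (high vs low phonotactic probability)."""
    row = FREQUENCY_TABLE.loc[scope]
    return float(row["ts_freq"] / row["tk_freq"])


def stress_share(scope: str, which: str) -> float:
    """Share (0-1) of first- or second-stress frequency within a scope."""
    row = FREQUENCY_TABLE.loc[scope]
    tot = row["sylstr1_freq"] + row["sylstr2_freq"]
    col = "sylstr1_freq" if which == "SylStr1" else "sylstr2_freq"
    return float(row[col] / tot)
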