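"""Trial selection and cross-condition count equalization.

Deviants occurring after only one standard are excluded; the standard
immediately preceding each kept deviant is selected as its comparison
trial.  Under the balanced default design (144 deviants per type spread
equally over separations 1-8) this retains exactly 126 deviants per type
and 252 preceding standards per condition.  Counts are then equalized to
the smallest kept-deviant count over all eight deviant cells of a
participant, with a single shared standard subset per condition so both
deviant types are compared against the same standard trials.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import Epochs


class SelectionError(ValueError):
    pass


SELECTION_COLUMNS = [
    "condition", "index", "stimulus", "role", "selected", "reason", "paired_deviant_index",
]


def select_analysis_trials(ep: Epochs) -> pd.DataFrame:
    """Per-trial selection table for one condition block.

    A deviant is selected iff it was preceded by >= 2 standards since the
    previous deviant and survived artifact screening; a standard is
    selected iff it immediately precedes a selected deviant and itself
    survived screening (no replacement is sought otherwise).
    """
    meta = ep.metadata
    n = len(meta)
    roles = meta["role"].to_numpy()
    kept = meta["kept"].to_numpy(dtype=bool)
    selected = np.zeros(n, dtype=bool)
    reason = np.array([""] * n, dtype=object)
    paired = np.full(n, -1, dtype=int)

    run = 0  # standards since previous deviant (or block start)
    for i in range(n):
        if roles[i] == "SD":
            run += 1
            reason[i] = "not_preceding"
            continue
        gap = run
        run = 0
        if gap < 2:
            reason[i] = "after_single_standard"
            continue
        if not kept[i]:
            reason[i] = f"rejected_{meta['reason'].iloc[i]}"
            continue
        selected[i] = True
        reason[i] = "deviant"
        j = i - 1  # immediately preceding standard (gap >= 2 guarantees SD)
        if kept[j]:
            selected[j] = True
            reason[j] = "preceding_standard"
            paired[j] = i
        else:
            reason[j] = f"rejected_{meta['reason'].iloc[j]}"

    out = meta[["condition", "index", "stimulus", "role"]].copy()
    out["selected"] = selected
    out["reason"] = reason
    out["paired_deviant_index"] = paired
    return out


def _cell_key(condition: str, role: str) -> str:
    return f"{condition}:{role}"


def equalize_counts(
    selections: dict[str, pd.DataFrame], seed: int = 0
) -> tuple[pd.DataFrame, int]:
    """Equalize analysis-trial counts across all deviant cells.

    ``selections`` maps condition id -> table from
    :func:`select_analysis_trials`.  N is the minimum selected-deviant
    count over the 8 (condition x deviant type) cells; every deviant cell
    and every condition's standard pool is subsampled without replacement
    (seeded) to exactly N.  Returns the combined table with an
    ``equalized`` column, and N.
    """
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    for cond, tab in selections.items():
        for role in ("FD", "TD"):
            counts[_cell_key(cond, role)] = int(
                ((tab["role"] == role) & tab["selected"]).sum()
            )
    empty = [k for k, v in counts.items() if v == 0]
    if empty:
        raise SelectionError(f"deviant cell(s) with zero kept trials: {', '.join(sorted(empty))}")
    n_eq = min(counts.values())

    frames = []
    for cond in sorted(selections):
        tab = selections[cond].copy()
        equalized = np.zeros(len(tab), dtype=bool)
        for role in ("FD", "TD"):
            idx = np.flatnonzero((tab["role"] == role).to_numpy() & tab["selected"].to_numpy())
            chosen = rng.choice(idx, size=n_eq, replace=False)
            equalized[np.sort(chosen)] = True
        sd_idx = np.flatnonzero((tab["role"] == "SD").to_numpy() & tab["selected"].to_numpy())
        if len(sd_idx) < n_eq:
            raise SelectionError(
                f"standard pool of condition {cond} has only {len(sd_idx)} trials, "
                f"fewer than the equalization target {n_eq}"
            )
        chosen = rng.choice(sd_idx, size=n_eq, replace=False)
        equalized[np.sort(chosen)] = True
        tab["equalized"] = equalized
        frames.append(tab)
    return pd.concat(frames, ignore_index=True), n_eq
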