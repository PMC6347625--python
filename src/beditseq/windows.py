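"""Editing-window width, positional selectivity and editor comparison tables.

The width rule is this package's own formalization: the window is the minimal
contiguous PAM-relative interval containing every position whose C-to-T
activity reaches ``rel_threshold`` times the profile maximum (default 30%).
The rule is scale-free — multiplying a profile by a constant leaves the
window unchanged — and is emitted alongside every width so the number is
never reported without its definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "EditingWindow",
    "Selectivity",
    "window_width",
    "positional_selectivity",
    "editor_comparison",
]


@dataclass(frozen=True)
class EditingWindow:
    offsets: tuple[int, int] | None  # inclusive (min_offset, max_offset); None if empty
    width: int
    threshold_rule: str

    def contains(self, offset: int) -> bool:
        return (self.offsets is not None
                and self.offsets[0] <= offset <= self.offsets[1])


@dataclass(frozen=True)
class Selectivity:
    """Fold preference for the focal position over its best neighbor.

    ``capped=True`` means every neighbor had zero activity and ``fold`` is the
    reporting lower bound ``focal/epsilon`` (serialize as ">= fold"), never
    infinity.  ``fold=None`` (NA) when focal and neighbors are all zero.
    """

    fold: float | None
    capped: bool = False

    def __str__(self) -> str:
        if self.fold is None:
            return "NA"
        return f">={self.fold:g}" if self.capped else f"{self.fold:g}"


def window_width(
    profile: dict[int, float], rel_threshold: float = 0.3
) -> EditingWindow:
    if not profile:
        raise ValueError("empty profile")
    if not all(0.0 <= v <= 1.0 for v in profile.values()):
        raise ValueError("profile values must lie in [0, 1]")
    rule = f"offsets with activity >= {rel_threshold:g} * max(profile), minimal covering interval"
    peak = max(profile.values())
    if peak == 0.0:
        return EditingWindow(offsets=None, width=0, threshold_rule=rule)
    above = [off for off, v in profile.items() if v >= rel_threshold * peak]
    lo, hi = min(above), max(above)
    return EditingWindow(offsets=(lo, hi), width=hi - lo + 1, threshold_rule=rule)


def positional_selectivity(
    profile: dict[int, float],
    focal: int,
    neighbors: list[int] | None = None,
    epsilon: float = 1e-4,
) -> Selectivity:
    """Fold-preference of the focal C over the most-edited neighbor C.

    ``neighbors`` defaults to every other profiled position (the other target
    cytidines of the protospacer).
    """
    if focal not in profile:
        raise ValueError(f"focal offset {focal} not in profile")
    if neighbors is None:
        neighbors = [off for off in profile if off != focal]
    if not neighbors or any(n not in profile for n in neighbors):
        raise ValueError("neighbors must be a non-empty subset of the profile")
    best = max(profile[n] for n in neighbors)
    f = profile[focal]
    if best > 0.0:
        return Selectivity(fold=f / best)
    if f == 0.0:
        return Selectivity(fold=None)
    return Selectivity(fold=f / epsilon, capped=True)


def editor_comparison(
    profiles: dict[str, dict[int, float]],
    focal: int | None = None,
    single_edit_fractions: dict[str, float | None] | None = None,
    rel_threshold: float = 0.3,
) -> pd.DataFrame:
    """One summary row per editor: peak activity and position, window, selectivity.

    All profiles must share one offset domain.  ``focal`` defaults to the
    consensus argmax offset across editors; per-editor single-edit fractions
    are attached when supplied.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    domains = {frozenset(p) for p in profiles.values()}
    if len(domains) != 1:
        raise ValueError("profiles have mismatched offset domains")
    if focal is None:
        votes = pd.Series(
            [max(p, key=p.get) for p in profiles.values()]  # type: ignore[arg-type]
        )
        focal = int(votes.mode().iloc[0])
    rows = []
    for label, prof in profiles.items():
        argmax = max(prof, key=prof.get)  # type: ignore[arg-type]
        win = window_width(prof, rel_threshold=rel_threshold)
        sel = positional_selectivity(prof, focal) if len(prof) > 1 else Selectivity(None)
        row = {
            "editor": label,
            "max_activity": prof[argmax],
            "argmax_offset": argmax,
            "window_width": win.width,
            "window_rule": win.threshold_rule,
            "focal_offset": focal,
            "selectivity": str(sel),
        }
        if single_edit_fractions is not None:
            row["single_edit_fraction"] = single_edit_fractions.get(label)
        rows.append(row)
    return pd.DataFrame(rows)
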