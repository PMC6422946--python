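"""Compact letter displays for multiple-comparison results.

Groups sharing at least one letter are not significantly different.
Implementation follows the insert-and-absorb algorithm: start from a
single letter covering all groups, split a letter whenever it joins a
significantly different pair, then drop letters that are subsets of
another.  Letters are assigned in first-seen order over groups sorted by
descending mean, so the highest group always carries "a".
"""

from __future__ import annotations

import string
from typing import Hashable, Iterable, Sequence


def compact_letter_display(
    groups: Sequence[Hashable],
    significant_pairs: Iterable[tuple[Hashable, Hashable]],
    order: Sequence[Hashable] | None = None,
) -> dict[Hashable, str]:
    """Assign letters so that exactly the non-significant pairs share one.

    Parameters
    ----------
    groups
        All group labels.
    significant_pairs
        Unordered pairs declared significantly different.
    order
        Display order (e.g. by descending group mean); defaults to
        ``groups`` order.
    """
    groups = list(groups)
    order = list(order) if order is not None else groups
    sig = {frozenset(p) for p in significant_pairs}
    columns: list[set[Hashable]] = [set(groups)]
    for pair in sig:
        a, b = tuple(pair)
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                columns.append(col - {a})
                columns.append(col - {b})
        # absorb: drop any column contained in another
        columns = [c for c in columns if c and not any(c < d for d in columns if d is not c)]
        # deduplicate
        uniq: list[set[Hashable]] = []
        for c in columns:
            if c not in uniq:
                uniq.append(c)
        columns = uniq
    # order columns by the first group (in display order) they contain
    pos = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda c: min(pos[g] for g in c))
    alphabet = string.ascii_lowercase
    out: dict[Hashable, str] = {g: "" for g in groups}
    for i, col in enumerate(columns):
        letter = alphabet[i] if i < len(alphabet) else f"l{i}"
        for g in order:
            if g in col:
                out[g] += letter
    return out
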