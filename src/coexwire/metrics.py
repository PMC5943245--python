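"""Small agreement metrics for recovered vs planted structure."""

from __future__ import annotations

from collections.abc import Iterable


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard index |a & b| / |a | b| of two sample sets."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def best_match_jaccard(
    recovered: list[list[str]], planted: dict[str, list[str]]
) -> dict[str, float]:
    """Match each planted group to its best-overlapping recovered group.

    Returns planted-name -> Jaccard with its best match (0.0 when nothing
    was recovered).  Matching is greedy by descending Jaccard, each
    recovered group used at most once.
    """
    pairs = []
    for name, members in planted.items():
        for i, rec in enumerate(recovered):
            pairs.append((jaccard(members, rec), name, i))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    out = {name: 0.0 for name in planted}
    used_rec: set[int] = set()
    used_name: set[str] = set()
    for j, name, i in pairs:
        if name in used_name or i in used_rec:
            continue
        out[name] = j
        used_name.add(name)
        used_rec.add(i)
    return out
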