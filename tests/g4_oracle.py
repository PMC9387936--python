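"""Independent brute-force oracle for quadruplex pattern matching.

A hand-written recursive backtracking matcher for the structure
"(G-tract >=3, loop 1-12 word chars) x >=3, final G-tract >=3" that
simulates leftmost-first, greedy-with-backtracking semantics and span
consumption directly, without using the `re` module. Preference order:
at every choice point longer comes first (greedy), another tract+loop
repetition is preferred over stopping, and inside a repetition the loop
backtracks before the G-tract. Failures are memoised on (position,
repetitions capped at 3), which preserves the preference order while
keeping the search polynomial on G-dense strings.
"""

from __future__ import annotations

import string

_WORD = frozenset(string.ascii_letters + string.digits + "_")
_G = frozenset("gG")


def _grun_ends(s: str, i: int):
    """Ends of G-tracts starting at i, longest first, minimum 3."""
    j = i
    n = len(s)
    while j < n and s[j] in _G:
        j += 1
    return range(j, i + 2, -1)  # j, j-1, ..., i+3


def _loop_ends(s: str, i: int):
    """Ends of loops (1-12 word characters) starting at i, longest first."""
    j = i
    n = len(s)
    while j < n and j - i < 12 and s[j] in _WORD:
        j += 1
    return range(j, i, -1)


def _match_end(s: str, start: int, fail: set) -> int | None:
    """End of the greedy match beginning exactly at ``start``, or None."""

    def rec(pos: int, reps: int) -> int | None:
        key = (pos, min(reps, 3))
        if key in fail:
            return None
        # greedy: try to consume one more (G-tract, loop) repetition first
        for g_end in _grun_ends(s, pos):
            for loop_end in _loop_ends(s, g_end):
                end = rec(loop_end, reps + 1)
                if end is not None:
                    return end
        # then close with the final G-tract (longest first; any works)
        if reps >= 3:
            for g_end in _grun_ends(s, pos):
                return g_end
        fail.add(key)
        return None

    return rec(start, 0)


def oracle_find_g4(s: str) -> list[tuple[int, int, str]]:
    """All non-overlapping matches, leftmost-first with consumption."""
    out: list[tuple[int, int, str]] = []
    fail: set = set()
    i = 0
    n = len(s)
    while i < n:
        end = _match_end(s, i, fail)
        if end is None:
            i += 1
        else:
            out.append((i, end, s[i:end]))
            i = end  # consume the span; memo entries stay valid, they
            # depend only on (position, remaining repetitions)
    return out
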