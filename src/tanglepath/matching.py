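"""Multi-pattern exact matching over arbitrary hashable label alphabets.

Read walks are sequences of oriented-edge labels, not characters, so the
classic Aho–Corasick automaton is built here over tuples of hashable labels:
goto function as dicts, failure links by BFS, output sets merged along
failure links.  Matching a text of length n against all patterns costs
O(n + total pattern length + matches).
"""

from __future__ import annotations

from collections import deque
from typing import Hashable, Iterable, Sequence


class AhoCorasick:
    """Automaton over sequences of hashable labels.

    Patterns are registered with integer ids; ``search`` returns the set of
    pattern ids occurring in a text as contiguous subsequences.
    """

    def __init__(self, patterns: Iterable[Sequence[Hashable]]):
        self._goto: list[dict[Hashable, int]] = [{}]
        self._fail: list[int] = [0]
        self._output: list[set[int]] = [set()]
        self._n_patterns = 0
        for pattern in patterns:
            self._add(tuple(pattern))
        self._build_failure_links()

    def _add(self, pattern: tuple) -> None:
        if not pattern:
            raise ValueError("empty pattern")
        state = 0
        for label in pattern:
            nxt = self._goto[state].get(label)
            if nxt is None:
                nxt = len(self._goto)
                self._goto[state][label] = nxt
                self._goto.append({})
                self._fail.append(0)
                self._output.append(set())
            state = nxt
        self._output[state].add(self._n_patterns)
        self._n_patterns += 1

    def _build_failure_links(self) -> None:
        queue: deque[int] = deque()
        for state in self._goto[0].values():
            self._fail[state] = 0
            queue.append(state)
        while queue:
            state = queue.popleft()
            for label, nxt in self._goto[state].items():
                queue.append(nxt)
                f = self._fail[state]
                while f and label not in self._goto[f]:
                    f = self._fail[f]
                self._fail[nxt] = self._goto[f].get(label, 0)
                if self._fail[nxt] == nxt:
                    self._fail[nxt] = 0
                self._output[nxt] |= self._output[self._fail[nxt]]

    @property
    def n_patterns(self) -> int:
        return self._n_patterns

    def search(self, text: Sequence[Hashable]) -> set[int]:
        """Ids of all patterns occurring as contiguous runs in ``text``."""
        found: set[int] = set()
        state = 0
        for label in text:
            while state and label not in self._goto[state]:
                state = self._fail[state]
            state = self._goto[state].get(label, 0)
            found |= self._output[state]
        return found
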