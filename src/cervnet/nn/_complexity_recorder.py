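"""Process-global recorder that layers report (multiplications, parameters) to.

The complexity report is built by running a forward pass inside :func:`recording`;
``Conv2d`` and ``Linear`` report their analytic multiplication counts for the actual
activation shapes they saw, so the accounting automatically tracks strides, padding
and branching topology.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import List, Optional, Tuple

_current: Optional["_Recorder"] = None


class _Recorder:
    def __init__(self, names):
        self.names = names  # id(module) -> dotted name
        self.entries: List[Tuple[str, str, int, int]] = []
        self.seen = set()

    def record(self, module, mults: int, params: int) -> None:
        key = id(module)
        name = self.names.get(key, type(module).__name__)
        # a module called twice (weight sharing) is charged per call for mults,
        # but its parameters only once
        if key in self.seen:
            params = 0
        self.seen.add(key)
        self.entries.append((name, type(module).__name__, int(mults), int(params)))


def active() -> bool:
    return _current is not None


def record(module, mults: int, params: int) -> None:
    if _current is not None:
        _current.record(module, mults, params)


@contextmanager
def recording(names):
    global _current
    rec = _Recorder(names)
    _current = rec
    try:
        yield rec
    finally:
        _current = None
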