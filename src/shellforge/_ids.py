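"""Process-wide allocator for model-unique node ids.

Every AST node carries an id of the form ``n<k>``. Ids are compared only for
persistence round-trips; structural equality of nodes ignores them. After
loading a persisted model the allocator is advanced past every id seen so
that freshly created nodes can never collide with loaded ones.
"""

from __future__ import annotations

import re
import threading

_lock = threading.Lock()
_next = 1
_ID_RE = re.compile(r"^n(\d+)$")


def new_id() -> str:
    global _next
    with _lock:
        value = _next
        _next += 1
    return f"n{value}"


def advance_past(ids) -> None:
    """Ensure future ids do not collide with any id in ``ids``."""
    global _next
    with _lock:
        for node_id in ids:
            m = _ID_RE.match(str(node_id))
            if m:
                _next = max(_next, int(m.group(1)) + 1)
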