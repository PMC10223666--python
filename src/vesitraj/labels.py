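"""Integer codes for leaflet membership, shared by generator and analyzers."""

UNASSIGNED = 0
INNER = 1
OUTER = 2

CODE_TO_NAME = {UNASSIGNED: "unassigned", INNER: "inner", OUTER: "outer"}
NAME_TO_CODE = {v: k for k, v in CODE_TO_NAME.items()}


def other_leaflet(code: int) -> int:
    if code == INNER:
        return OUTER
    if code == OUTER:
        return INNER
    raise ValueError("no opposite leaflet for 'unassigned'")
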