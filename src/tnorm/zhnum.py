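"""Chinese numeral conversion for the small magnitudes seen in clinical TEs.

Covers 一..九十九 plus the colloquial 两; larger magnitudes are written with
Arabic digits in discharge summaries and are handled as plain integers.
"""

from __future__ import annotations

_DIGITS = {"零": 0, "一": 1, "二": 2, "两": 2, "三": 3, "四": 4,
           "五": 5, "六": 6, "七": 7, "八": 8, "九": 9}

CN_NUM_CHARS = "零一二两三四五六七八九十"


def parse_number(token: str) -> int:
    """Parse an Arabic or Chinese (≤99) numeral string to an int."""
    token = token.strip()
    if not token:
        raise ValueError("empty numeral")
    if token.isdigit():
        return int(token)
    return _parse_cn(token)


def _parse_cn(token: str) -> int:
    if any(ch not in _DIGITS and ch != "十" for ch in token):
        raise ValueError(f"not a Chinese numeral: {token!r}")
    if "十" in token:
        tens_part, _, units_part = token.partition("十")
        tens = _DIGITS[tens_part] if tens_part else 1
        units = _DIGITS[units_part] if units_part else 0
        return tens * 10 + units
    if len(token) != 1:
        raise ValueError(f"unsupported Chinese numeral: {token!r}")
    return _DIGITS[token]
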