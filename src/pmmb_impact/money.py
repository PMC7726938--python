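"""Exact-decimal money helpers (BRL).

All model arithmetic runs on :class:`decimal.Decimal` so that sums over
thousands of physician-months stay exact; rounding (half-up, the spreadsheet
convention) happens only where a figure is displayed or a final total is
reported.
"""

from __future__ import annotations

import re
from decimal import Decimal, ROUND_HALF_UP

CENT = Decimal("0.01")

_CURRENCY_PREFIX = re.compile(r"^\s*R?\$?\s*")


def brl(value: object) -> Decimal:
    """Coerce ``value`` to an exact Decimal amount of BRL.

    Accepts Decimals, ints, floats (converted via str, so only use for
    literals), and strings in either Brazilian ("15.809,57") or ISO
    ("15,809.57") notation, with an optional "R$" prefix and sign.
    """
    if isinstance(value, Decimal):
        return value
    if isinstance(value, int):
        return Decimal(value)
    if isinstance(value, float):
        return Decimal(str(value))
    if isinstance(value, str):
        return _parse_brl_string(value)
    raise TypeError(f"cannot interpret {value!r} as a BRL amount")


def _parse_brl_string(text: str) -> Decimal:
    s = _CURRENCY_PREFIX.sub("", text.strip()).replace(" ", "").replace(" ", "")
    neg = s.startswith("-") or (s.startswith("(") and s.endswith(")"))
    s = s.strip("()").lstrip("+-")
    if not s:
        raise ValueError(f"empty currency string: {text!r}")
    # The right-most separator is the decimal mark; all others are grouping.
    last_dot, last_comma = s.rfind("."), s.rfind(",")
    if last_dot >= 0 and last_comma >= 0:
        dec = "." if last_dot > last_comma else ","
    elif last_dot >= 0 or last_comma >= 0:
        sep = "." if last_dot >= 0 else ","
        tail = s.rpartition(sep)[2]
        # a repeated separator, or a single one followed by a 3-digit group,
        # is grouping ("48.500" -> 48500); otherwise it is the decimal mark
        dec = None if s.count(sep) > 1 or len(tail) == 3 else sep
    else:
        dec = None
    if dec is not None:
        group = "," if dec == "." else "."
        s = s.replace(group, "").replace(dec, ".")
    else:
        s = s.replace(".", "").replace(",", "")
    amount = Decimal(s)
    return -amount if neg else amount


def round_cents(value: Decimal) -> Decimal:
    """Round half-up to whole cents."""
    return value.quantize(CENT, rounding=ROUND_HALF_UP)


def fmt_brl(value: Decimal, locale: str = "iso") -> str:
    """Render with cents and thousands separators.

    ``iso`` gives "1,124,135,514.00"; ``br`` gives "1.124.135.514,00".
    """
    q = round_cents(Decimal(value))
    base = f"{q:,.2f}"
    if locale == "iso":
        return base
    if locale == "br":
        return base.replace(",", "\0").replace(".", ",").replace("\0", ".")
    raise ValueError(f"unknown locale {locale!r}")
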