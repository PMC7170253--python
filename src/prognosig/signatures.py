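"""Bundled canonical signatures.

The 20-gene pancreatic prognostic score (PPS20) is a signed sum of log
expression: 11 adverse genes are added and 9 favorable genes subtracted.
"""

from .types import Signature

#: The published PPS20 scoring formula, verbatim signed-sum form.
PPS20_FORMULA = (
    "ARNTL2-KANK1+MAP4K4+LDHA+SLC20A1+TRIO-ZNF557+EPS8-CBX7+RAB7A"
    "-POLR3H+STX16-PITPNA+TFG-CADPS2+ERRFI1+GSK3B-NDUFB2-C2orf42-MIA3"
)


def pps20() -> Signature:
    """The canonical PPS20 signature (20 genes: 11 adverse, 9 favorable)."""
    return Signature.from_formula("PPS20", PPS20_FORMULA, source="bundled")
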