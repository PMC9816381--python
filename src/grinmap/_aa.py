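"""Amino-acid code tables shared across modules."""

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA1_TO_3 = {one: three for three, one in AA3_TO_1.items()}
STANDARD_AA = frozenset(AA1_TO_3)


def to_one_letter(code: str) -> str:
    """Normalize a 1- or 3-letter residue code to its 1-letter form."""
    code = code.strip()
    if len(code) == 1:
        up = code.upper()
        if up in STANDARD_AA:
            return up
    else:
        cap = code.capitalize()
        if cap in AA3_TO_1:
            return AA3_TO_1[cap]
    raise ValueError(f"unknown residue code: {code!r}")


def to_three_letter(code: str) -> str:
    return AA1_TO_3[to_one_letter(code)]
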