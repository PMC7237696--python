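"""Substitution-channel conventions.

All single-base substitutions are reported on the pyrimidine strand: a
mutation whose reference base is a purine (A or G) is reverse-complemented
together with its flanking bases before classification.  The 96 channels are
ordered substitution-major (C>A, C>G, C>T, T>A, T>C, T>G), context-minor
(5' flank then 3' flank, each in A,C,G,T order), matching the convention of
the standard reference-signature catalogs.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = "CT"
PURINES = "AG"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Seven-type spectrum channels: C>T is split by CpG context (3' flank G on
#: the pyrimidine strand).
SPECTRUM7_TYPES = ("C>A", "C>G", "C>T at CpG", "C>T other", "T>A", "T>C", "T>G")

CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUB_TYPES
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS_96)}

#: Map channel index -> index of its substitution type in SUB_TYPES.
CHANNEL_SUB_TYPE = tuple(i // 16 for i in range(96))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def pyrimidine_context(five: str, ref: str, three: str, alt: str):
    """Collapse a stranded trinucleotide substitution onto the pyrimidine strand.

    Returns ``(five', ref', three', alt')`` where ``ref'`` is C or T.
    """
    if ref in PYRIMIDINES:
        return five, ref, three, alt
    return complement(three), complement(ref), complement(five), complement(alt)


def channel_name(five: str, ref: str, three: str, alt: str) -> str:
    f, r, t, a = pyrimidine_context(five, ref, three, alt)
    return f"{f}[{r}>{a}]{t}"


def channel_index(five: str, ref: str, three: str, alt: str) -> int:
    return CHANNEL_INDEX[channel_name(five, ref, three, alt)]


def parse_channel(name: str):
    """Split ``'A[C>T]G'`` into ``(five, ref, alt, three)``."""
    five = name[0]
    ref = name[2]
    alt = name[4]
    three = name[6]
    return five, ref, alt, three


def is_cpg_channel(name: str) -> bool:
    """True for C>T substitutions in an NpCpG context (pyrimidine strand)."""
    five, ref, alt, three = parse_channel(name)
    return ref == "C" and alt == "T" and three == "G"


#: For each of the 96 channels, its index in SPECTRUM7_TYPES.
CHANNEL_SPECTRUM7 = tuple(
    (2 if is_cpg_channel(name) else 3)
    if name[2:5] == "C>T"
    else {"C>A": 0, "C>G": 1, "T>A": 4, "T>C": 5, "T>G": 6}[name[2:5]]
    for name in CHANNELS_96
)
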