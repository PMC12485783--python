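"""Independent brute-force re-derivations used as oracles by the spectrum
classifier tests. Deliberately written in a different style from the
package implementation (hardcoded catalogs, naive scans)."""

import os

from allergome.variant_consensus import VariantCall

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s):
    return "".join(COMP[b] for b in reversed(s))


# The 78 canonical doublet-substitution channels, written out literally.
DBS78_CATALOG = [
    "AC>CA", "AC>CG", "AC>CT", "AC>GA", "AC>GG", "AC>GT", "AC>TA", "AC>TG",
    "AC>TT",
    "AT>CA", "AT>CC", "AT>CG", "AT>GA", "AT>GC", "AT>TA",
    "CC>AA", "CC>AG", "CC>AT", "CC>GA", "CC>GG", "CC>GT", "CC>TA", "CC>TG",
    "CC>TT",
    "CG>AT", "CG>GC", "CG>GT", "CG>TA", "CG>TC", "CG>TT",
    "CT>AA", "CT>AC", "CT>AG", "CT>GA", "CT>GC", "CT>GG", "CT>TA", "CT>TC",
    "CT>TG",
    "GC>AA", "GC>AG", "GC>AT", "GC>CA", "GC>CG", "GC>TA",
    "TA>AT", "TA>CG", "TA>CT", "TA>GC", "TA>GG", "TA>GT",
    "TC>AA", "TC>AG", "TC>AT", "TC>CA", "TC>CG", "TC>CT", "TC>GA", "TC>GG",
    "TC>GT",
    "TG>AA", "TG>AC", "TG>AT", "TG>CA", "TG>CC", "TG>CT", "TG>GA", "TG>GC",
    "TG>GT",
    "TT>AA", "TT>AC", "TT>AG", "TT>CA", "TT>CC", "TT>CG", "TT>GA", "TT>GC",
    "TT>GG",
]


def sbs96_oracle(seq, pos, ref, alt):
    """pos is 1-based; seq a contig string."""
    i = pos - 1
    left, right = seq[i - 1], seq[i + 1]
    assert seq[i] == ref
    if ref in ("A", "G"):
        left, right = COMP[right], COMP[left]
        ref, alt = COMP[ref], COMP[alt]
    return "%s[%s>%s]%s" % (left, ref, alt, right)


def dbs78_oracle(ref, alt):
    for cand_ref, cand_alt in ((ref, alt), (rc(ref), rc(alt)),
                               (ref, rc(alt)), (rc(ref), alt)):
        if "%s>%s" % (cand_ref, cand_alt) in DBS78_CATALOG:
            return "%s>%s" % (cand_ref, cand_alt)
    raise AssertionError("no canonical form for %s>%s" % (ref, alt))


def _copies_right(unit, flank):
    """Tandem copies of unit at the start of flank, by string growth."""
    grown, n = "", 0
    while True:
        grown += unit
        if flank.startswith(grown):
            n += 1
        else:
            return n


def id83_oracle(seq, variant):
    i = variant.pos - 1
    if variant.var_class == "DEL":
        piece = variant.ref[1:]
        after = seq[i + len(variant.ref):]
        before = seq[:i + 1]
        kind = "Del"
    else:
        piece = variant.alt[1:]
        after = seq[i + 1:]
        before = seq[:i + 1]
        kind = "Ins"
    n = len(piece)
    copies = _copies_right(piece, after)
    if n == 1:
        base = piece if piece in ("C", "T") else COMP[piece]
        return "1:%s:%s:%d" % (kind, base, min(copies, 5))
    lb = min(n, 5)
    if kind == "Ins":
        return "%d:Ins:R:%d" % (lb, min(copies, 5))
    if copies >= 1:
        return "%d:Del:R:%d" % (lb, min(copies, 5))
    mh_right = len(os.path.commonprefix([piece, after]))
    mh_left = len(os.path.commonprefix([piece[::-1], before[::-1]]))
    mh = min(max(mh_right, mh_left), n - 1)
    if mh >= 1:
        return "%d:Del:M:%d" % (lb, min(mh, 5))
    return "%d:Del:R:0" % lb


def random_variants(seq, rng, n, classes=("SNV", "DBS", "INS", "DEL"),
                    contig="chrS"):
    """Random genome-consistent variants away from contig edges."""
    out = []
    bases = "ACGT"
    for _ in range(n):
        klass = classes[int(rng.integers(len(classes)))]
        pos = int(rng.integers(10, len(seq) - 10))  # 1-based, interior
        i = pos - 1
        if klass == "SNV":
            ref = seq[i]
            alt = [b for b in bases if b != ref][int(rng.integers(3))]
            out.append(VariantCall(contig, pos, ref, alt))
        elif klass == "DBS":
            ref = seq[i:i + 2]
            alt = "".join([b for b in bases if b != r][int(rng.integers(3))]
                          for r in ref)
            out.append(VariantCall(contig, pos, ref, alt))
        elif klass == "INS":
            length = int(rng.integers(1, 6))
            ins = "".join(bases[int(rng.integers(4))] for _ in range(length))
            out.append(VariantCall(contig, pos, seq[i], seq[i] + ins))
        else:
            length = int(rng.integers(1, 7))
            ref = seq[i:i + 1 + length]
            out.append(VariantCall(contig, pos, ref, ref[0]))
    return out


def id83_grid_cases():
    """Constructed (sequence, variant) pairs covering the full indel
    category grid: every type x length bin x repeat/homopolymer bin x
    microhomology bin."""
    pad = "G" * 30
    anchor = len(pad)  # 1-based position of the last pad base
    cases = []
    for base in "CT":
        for copies in range(0, 7):
            seq = pad + base * (copies + 1) + pad
            cases.append((seq, VariantCall("chrS", anchor, "G" + base, "G")))
            seq2 = pad + base * copies + pad
            cases.append((seq2, VariantCall("chrS", anchor, "G", "G" + base)))
    for L in (2, 3, 4, 5, 6):
        unit = ("CATTAC" * 2)[:L]  # no G: pad never extends a repeat
        for copies in range(0, 7):
            seq = pad + unit * (copies + 1) + pad
            cases.append((seq, VariantCall("chrS", anchor, "G" + unit, "G")))
            seq2 = pad + unit * copies + pad
            cases.append((seq2, VariantCall("chrS", anchor, "G", "G" + unit)))
        for m in range(1, min(L - 1, 5) + 1):
            seq = pad + unit + unit[:m] + pad
            cases.append((seq, VariantCall("chrS", anchor, "G" + unit, "G")))
    return cases
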