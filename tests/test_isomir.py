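"""IsomiR classification: oracle agreement, cascade semantics, accounting."""

import numpy as np
import pytest

from urimir.isomir import (
    IsomiRCategory,
    analyze_unaligned,
    assign_read,
    classify_against_mature,
    coverage_filter,
    detect_primer_dimer,
    profile_sample,
)
from urimir.preprocess import SmallRNARead
from urimir.refio import MiRNARecord, ReferenceTier, SequenceDB
from urimir.synth import DEFAULT_ADAPTER3, DEFAULT_ADAPTER5

BASES = "ACGT"


# --- independent first-principles oracle -------------------------------------

def oracle_classify(read, mature):
    """Re-derivation of the category definitions, written as literal set
    membership tests (independent of the production precedence scan)."""
    if read == mature:
        return IsomiRCategory.IDENTICAL
    truncations = set()
    for k in range(1, 6):
        if len(mature) - k >= 1:
            truncations.add(mature[k:])
            truncations.add(mature[:-k])
    if read in truncations:
        return IsomiRCategory.SHORTER_PERFECT
    end_subs = set()
    for b in BASES:
        for variant in (b + mature[1:], mature[:-1] + b):
            if variant != mature and len(variant) == len(mature):
                end_subs.add(variant)
    if read in end_subs:
        return IsomiRCategory.END_SUBSTITUTION
    one_extra = {b + mature for b in BASES} | {mature + b for b in BASES}
    if read in one_extra:
        return IsomiRCategory.ONE_EXTRA_BASE
    two_extra = set()
    for b1 in BASES:
        for b2 in BASES:
            two_extra |= {b1 + b2 + mature, b1 + mature + b2, mature + b1 + b2}
    if read in two_extra:
        return IsomiRCategory.TWO_EXTRA_BASES
    internal = set()
    for pos in range(1, len(mature) - 1):
        for b in BASES:
            if b != mature[pos]:
                internal.add(mature[:pos] + b + mature[pos + 1 :])
    if read in internal:
        return IsomiRCategory.INTERNAL_MISMATCH
    return None


def all_variants(mature):
    """Every single-edit, <=2 end-extension and <=5 end-truncation variant."""
    variants = {mature}
    for pos in range(len(mature)):
        for b in BASES:
            variants.add(mature[:pos] + b + mature[pos + 1 :])
    for b in BASES:
        variants |= {b + mature, mature + b}
        for b2 in BASES:
            variants |= {b + b2 + mature, b + mature + b2, mature + b + b2}
    for k in range(1, 6):
        variants |= {mature[k:], mature[:-k]}
    return variants


def random_seq(rng, length):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def test_classifier_matches_oracle_exhaustively():
    """Exhaustive agreement over all variants of a fixed 20-nt mature."""
    rng = np.random.default_rng(7)
    mature = random_seq(rng, 20)
    for v in sorted(all_variants(mature)):
        assert classify_against_mature(v, mature) is oracle_classify(v, mature), v


def test_mutual_exclusivity_over_random_matures():
    """Each variant of each random 18-25 nt mature lands in exactly the
    category the first-principles oracle derives (never two)."""
    rng = np.random.default_rng(42)
    n_cases = 0
    for _ in range(10):
        mature = random_seq(rng, int(rng.integers(18, 26)))
        for v in all_variants(mature):
            got = classify_against_mature(v, mature)
            assert got is oracle_classify(v, mature)
            n_cases += 1
    assert n_cases > 1200


@pytest.mark.parametrize(
    "read,mature,expected",
    [
        ("AGAGGTAGTAGGTTGCATAGTT", "AGAGGTAGTAGGTTGCATAGTT", IsomiRCategory.IDENTICAL),
        # 17 of 22 nt prefix: 5 short -> shorter; 16 of 22: 6 short -> none
        ("ACGTACGTACGTACGTACGTAC"[:17], "ACGTACGTACGTACGTACGTAC", IsomiRCategory.SHORTER_PERFECT),
        ("ACGTACGTACGTACGTACGTAC"[:16], "ACGTACGTACGTACGTACGTAC", None),
        # position-10 flip is internal; position-22 (last) flip is an end substitution
        ("ACGTACGTATGTACGTACGTAC", "ACGTACGTACGTACGTACGTAC", IsomiRCategory.INTERNAL_MISMATCH),
        ("ACGTACGTACGTACGTACGTAA", "ACGTACGTACGTACGTACGTAC", IsomiRCategory.END_SUBSTITUTION),
        ("TACGTACGTACGTACGTACGTAC", "ACGTACGTACGTACGTACGTAC", IsomiRCategory.ONE_EXTRA_BASE),
        ("TTACGTACGTACGTACGTACGTAC", "ACGTACGTACGTACGTACGTAC", IsomiRCategory.TWO_EXTRA_BASES),
        ("TACGTACGTACGTACGTACGTACT", "ACGTACGTACGTACGTACGTAC", IsomiRCategory.TWO_EXTRA_BASES),
    ],
)
def test_classify_definition_cases(read, mature, expected):
    assert classify_against_mature(read, mature) is expected


# --- cascade -----------------------------------------------------------------

def _tier(species, records):
    return ReferenceTier(species, records)


def test_tier_order_rat_wins_over_mouse():
    seq = "ACGTACGTACGTACGTACGTAC"
    rat = _tier("rat", [MiRNARecord("rno-x-5p", "rat", seq)])
    mouse = _tier("mouse", [MiRNARecord("mmu-x-5p", "mouse", seq)])
    call = assign_read(seq, [rat, mouse])
    assert call.mirna_id == "rno-x-5p" and call.species == "rat"


def test_two_identical_rat_matures_make_read_ambiguous():
    seq = "ACGTACGTACGTACGTACGTAC"
    rat = _tier(
        "rat",
        [MiRNARecord("rno-a-5p", "rat", seq), MiRNARecord("rno-b-5p", "rat", seq)],
    )
    call = assign_read(seq, [rat])
    assert call is not None and not call.unique and call.mirna_id is None


def test_ambiguous_in_first_tier_does_not_fall_through():
    seq = "ACGTACGTACGTACGTACGTAC"
    rat = _tier(
        "rat",
        [MiRNARecord("rno-a-5p", "rat", seq), MiRNARecord("rno-b-5p", "rat", seq)],
    )
    mouse = _tier("mouse", [MiRNARecord("mmu-a-5p", "mouse", seq)])
    call = assign_read(seq, [rat, mouse])
    assert call.species == "rat" and not call.unique


def test_precursor_substring_call(tiers):
    rec = tiers[0].records[0]
    # a 20-nt window straddling the mature/flank boundary is a precursor-only hit
    p = rec.precursor_seq
    start = p.index(rec.mature_seq) + len(rec.mature_seq) - 8
    frag = p[start : start + 20]
    call = assign_read(frag, [tiers[0]])
    assert call is not None
    assert call.category is IsomiRCategory.PRECURSOR
    assert call.mirna_id == rec.mirna_id


def test_cascade_monotonicity(tiers):
    """Adding later tiers never changes assignments made by earlier tiers."""
    rat = tiers[0]
    rng = np.random.default_rng(5)
    seqs = [r.mature_seq for r in rat.records[:10]]
    seqs += [random_seq(rng, 22) for _ in range(10)]
    for seq in seqs:
        first = assign_read(seq, [rat])
        if first is not None:
            both = assign_read(seq, list(tiers))
            assert (both.mirna_id, both.category, both.species) == (
                first.mirna_id,
                first.category,
                first.species,
            )


def test_assign_vs_pairwise_scan_on_cascade(tiers):
    """Indexed assignment equals a record-by-record classify scan."""
    rng = np.random.default_rng(9)
    rat = tiers[0]
    precedence = list(IsomiRCategory)[:-1]
    reads = []
    for rec in rat.records[:8]:
        m = rec.mature_seq
        reads += [m, m[2:], "T" + m, m[:10] + "A" + m[11:]]
    reads += [random_seq(rng, 21) for _ in range(20)]
    for seq in reads:
        got = assign_read(seq, [rat])
        # brute force: best category over all records
        best, winners = None, []
        for rec in rat.records:
            cat = classify_against_mature(seq, rec.mature_seq)
            if cat is None:
                continue
            if best is None or precedence.index(cat) < precedence.index(best):
                best, winners = cat, [rec.mirna_id]
            elif cat is best:
                winners.append(rec.mirna_id)
        if best is None:
            prec_hits = [
                r.mirna_id
                for r in rat.records
                if r.precursor_seq and seq in r.precursor_seq
            ]
            if not prec_hits:
                assert got is None
                continue
            assert got.category is IsomiRCategory.PRECURSOR
            continue
        assert got.category is best
        if len(winners) == 1:
            assert got.unique and got.mirna_id == winners[0]
        else:
            assert not got.unique


def test_empty_tier_list_errors():
    with pytest.raises(ValueError):
        assign_read("ACGTACGTACGTACGTACGT", [])


# --- terminal labelling ------------------------------------------------------

def _read(seq, read_id="r"):
    return SmallRNARead(read_id, seq, [38] * len(seq))


def test_detect_primer_dimer_cases():
    dimer = SmallRNARead("d", DEFAULT_ADAPTER5 + DEFAULT_ADAPTER3, [38] * 40)
    assert detect_primer_dimer(dimer, DEFAULT_ADAPTER5, DEFAULT_ADAPTER3)
    genuine = _read("ACGTACGTACGTACGTACGTAC" + DEFAULT_ADAPTER3)
    assert not detect_primer_dimer(genuine, DEFAULT_ADAPTER5, DEFAULT_ADAPTER3)


def test_profile_conservation_and_order(tiers, dbs):
    rat = tiers[0]
    reads = (
        [_read(rec.mature_seq, f"m{i}") for i, rec in enumerate(rat.records[:5])]
        + [_read(dbs["exon"].sequences["exon_1"][10:32], "e0")]
        + [_read("ACG", "short")]  # primer-dimer residue
        + [_read("ACGTACGTACGTACGTACGTAC", "u0")]
    )
    profile, unaligned = profile_sample(reads, list(tiers), [dbs["other_ncrna"], dbs["exon"]])
    assert sum(profile.class_totals.values()) == profile.total_clean == len(reads)
    assert profile.class_totals["miRs"] == 5
    assert profile.class_totals["exon"] == 1
    assert profile.class_totals["primer_dimer"] == 1
    assert profile.class_totals["unaligned"] == 1
    assert [r.read_id for r in unaligned] == ["u0"]


def test_all_primer_dimer_input_gives_zero_mirna(tiers):
    reads = [_read("ACGT", f"d{i}") for i in range(5)]
    profile, _ = profile_sample(reads, list(tiers))
    assert profile.class_totals.get("miRs", 0) == 0
    assert profile.total_mirna_mapped == 0


def test_analyze_unaligned_cascade_order_and_top_table(dbs):
    wheat = dbs["wheat"]
    corn = dbs["corn"]
    shared = wheat.sequences["wheat_1"][0:20]
    corn_with_shared = SequenceDB("corn", dict(corn.sequences, extra=shared))
    reads = [_read(shared, f"w{i}") for i in range(3)]
    reads += [_read(corn.sequences["corn_1"][5:25], "c0")]
    reads += [_read("ACGTACGTACGTACGTACGTA", f"x{i}") for i in range(5)]
    report = analyze_unaligned(reads, [wheat, corn_with_shared, dbs["soybean"]], top_k=3)
    assert report.per_genome["wheat"] == 3  # shared sequence counted for wheat only
    assert report.per_genome["corn"] == 1
    top_seq, count, frac = report.top_sequences[0]
    assert top_seq == "ACGTACGTACGTACGTACGTA" and count == 5
    assert frac == pytest.approx(5 / 9)


def test_analyze_unaligned_empty_pool(dbs):
    report = analyze_unaligned([], [dbs["wheat"]])
    assert report.n_unaligned == 0 and report.top_sequences == []


def test_dominant_unaligned_sequence_fraction(dbs):
    # a pool where one sequence is 45 of 100 reads tops the table at 0.45
    seq = "ACGTACGTACGTACGTACGT"
    rng = np.random.default_rng(3)
    reads = [_read(seq, f"a{i}") for i in range(45)]
    reads += [_read(random_seq(rng, 21), f"b{i}") for i in range(55)]
    report = analyze_unaligned(reads, [], top_k=1)
    assert report.top_sequences[0][0] == seq
    assert report.top_sequences[0][2] == pytest.approx(0.45)


@pytest.mark.parametrize(
    "query,aligned,expected",
    [(20, 18, True), (20, 17, False), (20, 20, True)],  # 0.85 is NOT > 0.85
)
def test_coverage_filter_strict_inequality(query, aligned, expected):
    assert coverage_filter(query, aligned) is expected
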