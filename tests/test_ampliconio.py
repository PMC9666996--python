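"""Window location, base counting, and coordinate conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abequant import (
    AmbiguousPlacementError,
    CdnaAnchor,
    GenomicAnchor,
    NoReadsLocatedError,
    TargetSite,
    WindowCounts,
    count_bases,
    locate_window,
    protospacer_to_cdna,
    protospacer_to_genomic,
    revcomp,
)
from abequant.ampliconio import WINDOW_LEN

from conftest import make_counts


class TestTargetSite:
    def test_validation_rejects_bad_geometry(self):
        with pytest.raises(ValueError):
            TargetSite(protospacer="ACGT", pam="AGG")  # not 20 nt
        with pytest.raises(ValueError):
            TargetSite(protospacer="A" * 20, pam="ATT")  # PAM not NGG
        with pytest.raises(ValueError):
            TargetSite(protospacer="A" * 20, pam="AGG", target_position=1)  # outside window
        with pytest.raises(ValueError):
            TargetSite(protospacer="A" * 20, pam="AGG", window=(3, 25))

    def test_window_reference_and_excluded_positions(self, site):
        assert site.window_reference == site.protospacer + site.pam
        # editing window 3-9 and the PAM N (window position 21) never count
        # as mismatches
        assert site.excluded_positions == frozenset(range(3, 10)) | {21}


class TestCoordinates:
    def test_genomic_mapping_matches_printed_anchors(self, site):
        assert protospacer_to_genomic(site, 8) == ("chr3", 48_580_586)
        assert protospacer_to_genomic(site, 3) == ("chr3", 48_580_581)
        # anchor position maps to the anchor coordinate itself
        assert protospacer_to_genomic(site, 8)[1] == site.genomic_anchor.coordinate

    def test_cdna_mapping_matches_printed_anchors(self, site):
        assert protospacer_to_cdna(site, 8) == 5047
        assert protospacer_to_cdna(site, 3) == 5052

    def test_mappings_are_affine_and_injective(self, site):
        genomic = [protospacer_to_genomic(site, p)[1] for p in range(1, 21)]
        cdna = [protospacer_to_cdna(site, p) for p in range(1, 21)]
        assert len(set(genomic)) == 20 and len(set(cdna)) == 20
        assert set(np.diff(genomic)) == {site.genomic_anchor.sign}
        assert set(np.diff(cdna)) == {-site.cdna_anchor.orientation}
        assert genomic[7] - genomic[2] == 5
        assert cdna[2] - cdna[7] == 5

    def test_out_of_range_position_rejected(self, site):
        for p in (0, 21):
            with pytest.raises(ValueError):
                protospacer_to_genomic(site, p)
            with pytest.raises(ValueError):
                protospacer_to_cdna(site, p)


class TestLocateWindow:
    def test_identity_placement_on_reference_read(self, site, reference_read):
        placement = locate_window(reference_read, site)
        assert placement is not None
        # demo protospacer is on the amplicon minus strand
        assert placement.orientation == "-"
        assert placement.mismatches == 0
        oriented = revcomp(reference_read)
        window = oriented[placement.offset : placement.offset + WINDOW_LEN]
        assert window == site.window_reference

    def test_fully_edited_read_keeps_identical_placement(self, site, reference_read):
        base = locate_window(reference_read, site)
        oriented = revcomp(reference_read)
        # convert every window-position adenine to G on the protospacer strand
        edited = list(oriented)
        for p in range(site.window[0], site.window[1] + 1):
            if edited[base.offset + p - 1] == "A":
                edited[base.offset + p - 1] = "G"
        read = revcomp("".join(edited))
        placement = locate_window(read, site)
        assert placement is not None
        assert (placement.offset, placement.mismatches) == (base.offset, 0)

    def test_random_read_is_not_located(self, site):
        rng = np.random.default_rng(0)
        read = "".join(rng.choice(list("ACGT"), size=80))
        assert locate_window(read, site, max_mismatch=2) is None

    def test_reverse_complement_read_gives_same_window(self, site, reference_read):
        fwd = locate_window(reference_read, site)
        rev = locate_window(revcomp(reference_read), site)
        seq_f = reference_read if fwd.orientation == "+" else revcomp(reference_read)
        seq_r = (
            revcomp(reference_read) if rev.orientation == "+" else reference_read
        )
        assert (
            seq_f[fwd.offset : fwd.offset + WINDOW_LEN]
            == seq_r[rev.offset : rev.offset + WINDOW_LEN]
        )

    def test_duplicated_window_is_ambiguous(self, site):
        read = site.window_reference + "TTTTT" + site.window_reference
        with pytest.raises(AmbiguousPlacementError):
            locate_window(read, site)

    def test_mismatch_budget_applies_outside_editable_positions(self, site):
        window = list(site.window_reference)
        window[0] = "C" if window[0] != "C" else "T"  # position 1, counted
        window[1] = "C" if window[1] != "C" else "T"  # position 2, counted
        read = "TTTTT" + "".join(window) + "GGGGG"
        assert locate_window(read, site, max_mismatch=2).mismatches == 2
        assert locate_window(read, site, max_mismatch=1) is None


class TestCountBases:
    def test_unedited_reads_reproduce_reference_columns(self, site, reference_read):
        counts = count_bases([reference_read] * 100, site)
        assert counts.reads_located == 100
        assert counts.reads_dropped == 0
        for pos in range(1, WINDOW_LEN + 1):
            assert counts.base_count(pos, site.base_at(pos)) == 100

    def test_column_sums_equal_reads_located(self, simulated_counts):
        treated, _ = simulated_counts
        sums = treated.counts.sum(axis=1)
        assert (sums == treated.reads_located).all()

    def test_matches_per_read_brute_force_tally(self, site, alleles):
        """Vectorized counting equals a literal per-read loop over 50 noisy reads."""
        from abequant import SeqNoise, example_edit_model, simulate_amplicon_reads

        reads = [
            str(r.seq)
            for r in simulate_amplicon_reads(
                alleles,
                example_edit_model(0.7, 0.3),
                SeqNoise(depth=50, sub_error=0.01, seed=3),
            )
        ]
        counts = count_bases(reads, site)

        brute = {
            (pos, base): 0 for pos in range(1, WINDOW_LEN + 1) for base in "ACGTN"
        }
        located = 0
        for read in reads:
            placement = locate_window(read, site)
            if placement is None:
                continue
            oriented = read if placement.orientation == "+" else revcomp(read)
            located += 1
            for pos in range(1, WINDOW_LEN + 1):
                b = oriented[placement.offset + pos - 1]
                brute[(pos, b if b in "ACGT" else "N")] += 1
        assert located == counts.reads_located
        for (pos, base), expected in brute.items():
            assert counts.base_count(pos, base) == expected

    def test_simulated_edit_rate_recovered_in_counts(self, site, alleles):
        from abequant import SeqNoise, example_edit_model, simulate_amplicon_reads

        reads = simulate_amplicon_reads(
            alleles,
            example_edit_model(0.9, 0.0),
            SeqNoise(depth=4000, sub_error=0.0, seed=5),
        )
        counts = count_bases(reads, site)
        g_frac = counts.base_count(8, "G") / counts.informative(8)
        # expectation 0.5 (wild-type allele) + 0.5 * 0.9
        se = np.sqrt(0.95 * 0.05 / 4000)
        assert abs(g_frac - 0.95) < 3 * se

    def test_no_located_reads_raises(self, site):
        with pytest.raises(NoReadsLocatedError):
            count_bases(["ACGT" * 20], site)

    def test_n_bases_are_tallied_but_not_informative(self, site, reference_read):
        placement = locate_window(reference_read, site)
        oriented = list(revcomp(reference_read))
        oriented[placement.offset + 7] = "N"  # window position 8
        counts = count_bases([revcomp("".join(oriented))], site)
        assert counts.base_count(8, "N") == 1
        assert counts.informative(8) == 0
        assert counts.reads_located == 1


class TestCountsTSV:
    def test_round_trip(self, tmp_path, simulated_counts, site):
        treated, _ = simulated_counts
        path = tmp_path / "counts.tsv"
        treated.to_tsv(path)
        loaded = WindowCounts.from_tsv(path, site)
        assert (loaded.counts == treated.counts).all()
        assert loaded.reads_located == treated.reads_located
        assert loaded.reference_bases == treated.reference_bases

    def test_missing_column_rejected(self, tmp_path, simulated_counts, site):
        treated, _ = simulated_counts
        df = treated.to_frame().drop(columns=["N"])
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing columns"):
            WindowCounts.from_tsv(path, site)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(1, 20))
def test_affine_coordinate_round_trip(position):
    """Genomic and cDNA maps stay mutually consistent at every position."""
    site = TargetSite(
        protospacer="GTACCTGACGTCGTCGGTCT",
        pam="CGG",
        target_position=8,
        genomic_anchor=GenomicAnchor("chr3", 8, 48_580_586, sign=1),
        cdna_anchor=CdnaAnchor(8, 5047, orientation=1),
    )
    _, g = protospacer_to_genomic(site, position)
    c = protospacer_to_cdna(site, position)
    # both maps are affine in position, so their sum here is constant
    assert g + c == 48_580_586 + 5047
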