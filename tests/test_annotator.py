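"""Hit finding, array merging, GFF3 round trips and binned density."""

import numpy as np
import pytest

from satmapper import (
    Assembly,
    RepeatArray,
    RepeatHit,
    SatDNAFamily,
    annotate_assembly,
    binned_density,
    find_monomer_hits,
    merge_hits_into_arrays,
    mutate_to_divergence,
    read_gff3,
    reverse_complement,
    write_bed6,
    write_gff3,
)

from conftest import random_dna


# --------------------------------------------------------------------------
# independent oracle: score the monomer at every genomic offset.  On
# substitution-only sequence the optimal semi-global alignment is gap-free
# (a gap column costs more than a mismatch), so per-offset Hamming identity
# is exact; overlap resolution repeats the declared rule.

def oracle_hits(monomer: str, chrom: str, min_identity: float):
    m = len(monomer)
    raw = []
    for strand, query in (("+", monomer), ("-", reverse_complement(monomer))):
        for i in range(len(chrom) - m + 1):
            window = chrom[i : i + m]
            matches = sum(a == b for a, b in zip(query, window))
            identity = 100.0 * matches / m
            if identity >= min_identity:
                raw.append((i, i + m, strand, identity))
    # drop strand-duplicate intervals, keep '+' first like the annotator
    seen, unique = set(), []
    for item in sorted(raw, key=lambda x: (x[0], x[1], x[2])):
        if (item[0], item[1], item[2]) not in seen:
            seen.add((item[0], item[1], item[2]))
            unique.append(item)
    unique.sort(key=lambda x: (-x[3], x[0], x[1], x[2]))
    kept = []
    for s, e, strand, ident in unique:
        if all(e <= s2 or e2 <= s for s2, e2, _, _ in kept):
            kept.append((s, e, strand, ident))
    return sorted(kept)


def make_family(monomer):
    return SatDNAFamily.from_monomer(
        monomer, genus="Chrysolina", species="americana", rank=1
    )


class TestFindMonomerHits:
    def test_random_sequence_has_no_hits(self, family_141, rng):
        chrom = random_dna(10_000, rng)
        assert find_monomer_hits(family_141, chrom, 70) == []
        assert oracle_hits(family_141.monomer, chrom, 70) == []

    def test_perfect_array_tiles_exactly(self, family_141, monomer_141, rng):
        chrom = random_dna(5000, rng) + monomer_141 * 10 + random_dna(5000, rng)
        hits = find_monomer_hits(family_141, chrom, 70)
        assert [(h.start, h.end) for h in hits] == [
            (5000 + 141 * i, 5000 + 141 * (i + 1)) for i in range(10)
        ]
        assert all(h.identity_percent == 100.0 and h.strand == "+" for h in hits)

    def test_reverse_complemented_array(self, family_141, monomer_141, rng):
        fwd = random_dna(5000, rng) + monomer_141 * 10 + random_dna(5000, rng)
        rev = random_dna(5000, rng) + reverse_complement(monomer_141 * 10) \
            + random_dna(5000, rng)
        hits = find_monomer_hits(family_141, rev, 70)
        assert [(h.start, h.end) for h in hits] == [
            (5000 + 141 * i, 5000 + 141 * (i + 1)) for i in range(10)
        ]
        assert all(h.strand == "-" for h in hits)
        del fwd

    def test_matches_bruteforce_oracle_on_diverged_arrays(
        self, family_141, monomer_141, rng
    ):
        copies = []
        for _ in range(30):
            c, _, _ = mutate_to_divergence(monomer_141, 0.12, 2.0, rng)
            copies.append(c)
        chrom = (
            random_dna(4000, rng)
            + "".join(copies[:15])
            + random_dna(2000, rng)
            + reverse_complement("".join(copies[15:]))
            + random_dna(4000, rng)
        )
        hits = find_monomer_hits(family_141, chrom, 70)
        expected = oracle_hits(monomer_141, chrom, 70)
        assert [(h.start, h.end, h.strand) for h in hits] == [
            (s, e, strand) for s, e, strand, _ in expected
        ]
        for h, (_, _, _, ident) in zip(hits, expected):
            assert h.identity_percent == pytest.approx(ident)

    def test_threshold_monotonicity(self, family_141, monomer_141, rng):
        copies = [
            mutate_to_divergence(monomer_141, 0.15, 2.0, rng)[0]
            for _ in range(20)
        ]
        chrom = random_dna(2000, rng) + "".join(copies) + random_dna(2000, rng)
        loose = {
            (h.start, h.end)
            for h in find_monomer_hits(family_141, chrom, 70)
        }
        strict = {
            (h.start, h.end)
            for h in find_monomer_hits(family_141, chrom, 85)
        }
        assert strict <= loose

    def test_mid_phase_array_is_found(self, family_141, monomer_141, rng):
        # array starts halfway through the consensus: full copies inside
        # the run must still be recovered (phase invariance)
        rolled = monomer_141[70:] + monomer_141[:70]
        chrom = random_dna(3000, rng) + rolled * 8 + random_dna(3000, rng)
        hits = find_monomer_hits(family_141, chrom, 70)
        covered = sum(h.end - h.start for h in hits)
        assert covered >= 7 * 141  # all interior copies
        assert all(3000 - 141 <= h.start and h.end <= 3000 + 8 * 141 + 141
                   for h in hits)

    def test_bad_threshold_rejected(self, family_141):
        with pytest.raises(ValueError):
            find_monomer_hits(family_141, "ACGT" * 100, 0)
        with pytest.raises(ValueError):
            find_monomer_hits(family_141, "ACGT" * 100, 101)


class TestShortMonomerTandems:
    def test_telomeric_run_detected(self, rng):
        fam = SatDNAFamily(name="CameSat035-5-tel", rank=35, rul=5,
                           monomer="TTAGG")
        chrom = random_dna(1000, rng) + "TTAGG" * 10 + random_dna(1000, rng)
        hits = find_monomer_hits(fam, chrom, 70)
        assert [(h.start, h.end) for h in hits] == [
            (1000 + 5 * i, 1000 + 5 * (i + 1)) for i in range(10)
        ]
        assert all(h.strand == "+" for h in hits)

    def test_minus_strand_run(self, rng):
        fam = SatDNAFamily(name="CameSat035-5-tel", rank=35, rul=5,
                           monomer="TTAGG")
        chrom = random_dna(500, rng) + "CCTAA" * 8 + random_dna(500, rng)
        hits = find_monomer_hits(fam, chrom, 70)
        assert len(hits) == 8
        assert all(h.strand == "-" for h in hits)

    def test_below_copy_floor_ignored(self):
        fam = SatDNAFamily(name="CameSat035-5-tel", rank=35, rul=5,
                           monomer="TTAGG")
        chrom = "C" * 200 + "TTAGG" * 3 + "C" * 200
        assert find_monomer_hits(fam, chrom, 70) == []


def _hit(family_id, start, end, strand="+", chrom="chr1", identity=100.0):
    return RepeatHit(
        family_id=family_id, chrom=chrom, start=start, end=end,
        strand=strand, identity_percent=identity,
    )


class TestMergeHits:
    def test_empty(self):
        assert merge_hits_into_arrays([], 141) == []

    def test_contiguous_hits_form_one_array(self):
        hits = [_hit("F", 141 * i, 141 * (i + 1)) for i in range(10)]
        arrays = merge_hits_into_arrays(hits, 141)
        assert len(arrays) == 1
        assert arrays[0].n_monomers == 10
        assert (arrays[0].start, arrays[0].end) == (0, 1410)

    def test_wide_gap_splits_arrays(self):
        # two hits separated by 3 x RUL: beyond a 1 x RUL merge gap
        hits = [_hit("F", 0, 141), _hit("F", 141 + 3 * 141, 141 + 4 * 141)]
        arrays = merge_hits_into_arrays(hits, 141)
        assert [a.n_monomers for a in arrays] == [1, 1]

    def test_strand_change_splits(self):
        hits = [_hit("F", 0, 141, "+"), _hit("F", 150, 291, "-")]
        assert len(merge_hits_into_arrays(hits, 141)) == 2

    def test_unsorted_input_rejected(self):
        hits = [_hit("F", 500, 641), _hit("F", 0, 141)]
        with pytest.raises(ValueError):
            merge_hits_into_arrays(hits, 141)

    def test_mixed_families_rejected(self):
        hits = [_hit("F", 0, 141), _hit("G", 200, 341)]
        with pytest.raises(ValueError):
            merge_hits_into_arrays(hits, 141)


class TestAnnotateAssembly:
    def test_families_recovered_on_their_chromosomes(self, rng):
        mono_a = random_dna(120, rng)
        mono_b = random_dna(150, rng)
        fam_a = SatDNAFamily.from_monomer(
            mono_a, genus="Chrysolina", species="americana", rank=1)
        fam_b = SatDNAFamily.from_monomer(
            mono_b, genus="Chrysolina", species="americana", rank=2)
        chr1 = random_dna(2000, rng) + mono_a * 8 + random_dna(2000, rng)
        chr2 = random_dna(2000, rng) + mono_b * 8 + random_dna(2000, rng)
        asm = Assembly(chromosomes=[("chr1", chr1), ("chr2", chr2)])
        ann = annotate_assembly([fam_a, fam_b], asm)
        assert {a.chrom for a in ann[fam_a.name]} == {"chr1"}
        assert {a.chrom for a in ann[fam_b.name]} == {"chr2"}
        assert ann[fam_a.name][0].n_monomers == 8

    def test_absent_family_gets_empty_list(self, family_141, rng):
        asm = Assembly(chromosomes=[("chr1", random_dna(5000, rng))])
        ann = annotate_assembly([family_141], asm)
        assert ann[family_141.name] == []

    def test_interleaved_families_both_recovered(self, rng):
        mono_a = random_dna(100, rng)
        mono_b = random_dna(100, rng)
        fam_a = SatDNAFamily.from_monomer(
            mono_a, genus="Chrysolina", species="americana", rank=1)
        fam_b = SatDNAFamily.from_monomer(
            mono_b, genus="Chrysolina", species="americana", rank=2)
        block = (mono_a * 5 + mono_b * 5) * 2
        chrom = random_dna(2000, rng) + block + random_dna(2000, rng)
        asm = Assembly(chromosomes=[("chr1", chrom)])
        ann = annotate_assembly([fam_a, fam_b], asm)
        bp_a = sum(a.length for a in ann[fam_a.name])
        bp_b = sum(a.length for a in ann[fam_b.name])
        assert bp_a == 10 * 100 and bp_b == 10 * 100
        starts_a = {a.start for a in ann[fam_a.name]}
        starts_b = {a.start for a in ann[fam_b.name]}
        assert starts_a == {2000, 2000 + 1000}
        assert starts_b == {2500, 3500}

    def test_empty_assembly_rejected(self, family_141):
        with pytest.raises(ValueError):
            annotate_assembly([family_141], Assembly(chromosomes=[]))

    def test_strand_symmetry(self, family_141, monomer_141, rng):
        copies = [
            mutate_to_divergence(monomer_141, 0.08, 2.0, rng)[0]
            for _ in range(10)
        ]
        chrom = random_dna(1500, rng) + "".join(copies) + random_dna(1500, rng)
        L = len(chrom)
        fwd = find_monomer_hits(family_141, chrom, 70)
        rev = find_monomer_hits(family_141, reverse_complement(chrom), 70)
        mirrored = sorted(
            (L - h.end, L - h.start, "-" if h.strand == "+" else "+")
            for h in rev
        )
        assert mirrored == [(h.start, h.end, h.strand) for h in fwd]


class TestGff3RoundTrip:
    def _random_arrays(self, n, rng):
        arrays = []
        pos = 0
        for i in range(n):
            pos += int(rng.integers(1, 500))
            length = int(rng.integers(50, 2000))
            arrays.append(
                RepeatArray(
                    family_id=f"CameSat{int(rng.integers(1, 166)):03d}-141",
                    chrom=f"chr{int(rng.integers(1, 4))}",
                    start=pos,
                    end=pos + length,
                    strand="+" if rng.integers(2) else "-",
                    n_monomers=int(rng.integers(1, 30)),
                    mean_identity_percent=float(
                        np.round(rng.uniform(70, 100), 4)
                    ),
                )
            )
            pos += length
        return arrays

    def test_round_trip_identity(self, tmp_path, rng):
        arrays = self._random_arrays(100, rng)
        path = tmp_path / "ann.gff3"
        write_gff3(arrays, path)
        assert read_gff3(path) == arrays

    def test_one_based_inclusive_coordinates(self, tmp_path):
        arr = RepeatArray(
            family_id="CameSat001-141", chrom="chr1", start=5000, end=6410,
            strand="+", n_monomers=10, mean_identity_percent=100.0,
        )
        path = tmp_path / "one.gff3"
        write_gff3([arr], path)
        line = [
            l for l in path.read_text().splitlines() if not l.startswith("#")
        ][0]
        fields = line.split("\t")
        assert (fields[3], fields[4]) == ("5001", "6410")
        assert fields[1] == "chrismapp" and fields[2] == "satellite_DNA"

    def test_empty_annotation_is_header_only(self, tmp_path):
        path = tmp_path / "empty.gff3"
        write_gff3([], path)
        assert path.read_text() == "##gff-version 3\n"
        assert read_gff3(path) == []

    def test_malformed_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\nchr1\tonly\tthree\n")
        with pytest.raises(ValueError, match=":2:"):
            read_gff3(path)
        path.write_text(
            "##gff-version 3\n"
            "chr1\tchrismapp\tsatellite_DNA\tX\t10\t.\t+\t.\tName=F\n"
        )
        with pytest.raises(ValueError, match=":2:"):
            read_gff3(path)

    def test_bed6_export(self, tmp_path):
        arr = RepeatArray(
            family_id="CameSat001-141", chrom="chr1", start=100, end=400,
            strand="-", n_monomers=2, mean_identity_percent=87.5,
        )
        path = tmp_path / "ann.bed"
        write_bed6([arr], path)
        assert path.read_text() == "chr1\t100\t400\tCameSat001-141\t875\t-\n"


class TestBinnedDensity:
    def _arr(self, start, end, family="F"):
        return RepeatArray(
            family_id=family, chrom="chr1", start=start, end=end,
            strand="+", n_monomers=1, mean_identity_percent=100.0,
        )

    def test_single_array_lands_in_its_bins(self):
        dens = binned_density([self._arr(200, 400)], 1000, bin_size=100)
        np.testing.assert_array_equal(
            dens["F"], [0, 0, 100, 100, 0, 0, 0, 0, 0, 0]
        )

    def test_straddling_array_splits_proportionally(self):
        dens = binned_density([self._arr(150, 250)], 400, bin_size=100)
        np.testing.assert_array_equal(dens["F"], [0, 50, 50, 0])

    def test_total_bp_conserved(self, rng):
        arrays = []
        pos = 0
        for _ in range(40):
            pos += int(rng.integers(1, 300))
            end = pos + int(rng.integers(1, 700))
            arrays.append(self._arr(pos, end))
            pos = end
        total = sum(a.length for a in arrays)
        dens = binned_density(arrays, pos + 10, bin_size=333)
        assert dens["F"].sum() == pytest.approx(total)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            binned_density([self._arr(0, 2000)], 1000, bin_size=100)
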