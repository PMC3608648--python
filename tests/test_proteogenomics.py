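"""Naive-database workflow: six-frame elements, digestion, classification,
retention concordance, genome mapping and anomaly adjudication."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoclades import proteogenomics as pg
from thermoclades import synthdata as sd
from thermoclades.types import (
    AnomalyRecord,
    CdsFeature,
    CdsSet,
    Contig,
    ContigSet,
    ObservedPeptide,
    Read,
    ReadSet,
)

dna = st.text(alphabet="ACGTN", min_size=0, max_size=60)
protein = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60)


class TestSixFrameElements:
    def test_known_six_frame_decomposition(self):
        els = {(e.frame, e.sequence) for e in pg.six_frame_elements("ATGAAATAA")}
        assert els == {
            (1, "MK"), (2, "N"), (3, "EI"), (-1, "LFH"), (-2, "YF"), (-3, "IS"),
        }

    def test_too_short_read_yields_nothing(self):
        assert pg.six_frame_elements("AT") == []

    def test_all_stop_frame_yields_no_element(self):
        els = pg.six_frame_elements("TAATAA")
        assert not [e for e in els if e.frame == 1]

    @settings(max_examples=60, derandomize=True)
    @given(dna)
    def test_split_is_lossless(self, read):
        """Concatenating a frame's elements with single stop separators
        reproduces that frame's full translation."""
        from Bio.Seq import Seq

        rc = str(Seq(read).reverse_complement())
        by_frame = {}
        for e in pg.six_frame_elements(read):
            by_frame.setdefault(e.frame, []).append(e)
        for frame in pg.FRAMES:
            src = read if frame > 0 else rc
            aa = pg.translate(src[abs(frame) - 1 :])
            rebuilt = list("*" * len(aa))
            for e in by_frame.get(frame, []):
                rebuilt[e.aa_offset : e.aa_offset + len(e.sequence)] = e.sequence
            assert "".join(rebuilt) == aa


def brute_force_digest(seq, missed, min_len, max_len):
    """Independent oracle: enumerate all substrings, keep those whose two
    boundaries are valid cleavage points (or sequence ends) with at most
    ``missed`` internal cleavage sites."""

    def cut_ok(m):  # a cleavage exists between m-1 and m
        return 0 < m < len(seq) and seq[m - 1] in "KR" and seq[m] != "P"

    out = []
    for i in range(len(seq)):
        for j in range(i + 1, len(seq) + 1):
            if not (i == 0 or cut_ok(i)):
                continue
            if not (j == len(seq) or cut_ok(j)):
                continue
            internal = sum(1 for m in range(i + 1, j) if cut_ok(m))
            if internal <= missed and min_len <= j - i <= max_len:
                out.append((seq[i:j], i))
    return sorted(out)


class TestTrypticDigest:
    @pytest.mark.parametrize(
        "seq,missed,expected",
        [
            ("MKRLDK", 0, ["MK", "R", "LDK"]),
            ("AKPGR", 0, ["AKPGR"]),  # K-P bond protected
            ("MKRLDK", 1, ["MK", "MKR", "R", "RLDK", "LDK"]),
        ],
    )
    def test_known_digests(self, seq, missed, expected):
        assert [p for p, _ in pg.tryptic_digest(seq, missed, 1, 50)] == expected

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            pg.tryptic_digest("", 0, 1, 50)

    def test_bad_length_bounds_are_an_error(self):
        with pytest.raises(ValueError):
            pg.tryptic_digest("MKR", 0, 10, 5)

    @settings(max_examples=100, derandomize=True)
    @given(protein, st.integers(0, 2))
    def test_matches_brute_force_enumeration(self, seq, missed):
        ours = sorted(pg.tryptic_digest(seq, missed, 1, 10**9))
        assert ours == brute_force_digest(seq, missed, 1, 10**9)


def _single_cds_genome(coding, strand="+", flank="GGGCCC"):
    if strand == "+":
        seq = flank + coding + flank
    else:
        from Bio.Seq import Seq

        seq = flank + str(Seq(coding).reverse_complement()) + flank
    contigs = ContigSet([Contig("c1", seq)])
    cds = CdsSet(
        [CdsFeature("g1", "c1", len(flank), len(flank) + len(coding), strand)]
    )
    return contigs, cds


class TestPeptideDatabases:
    def test_empty_reads_give_empty_naive_db(self):
        assert len(pg.build_naive_db(ReadSet([]))) == 0

    def test_duplicate_reads_are_idempotent_with_doubled_provenance(self):
        cfg = pg.DigestConfig(min_len=2)
        r = Read("r1", "ATGAAACGTCTGGATAAA")
        db1 = pg.build_naive_db(ReadSet([r]), cfg)
        db2 = pg.build_naive_db(ReadSet([r, Read("r2", r.seq)]), cfg)
        assert set(db1.entries) == set(db2.entries)
        assert all(len(db2.entries[k]) == 2 * len(db1.entries[k]) for k in db1.entries)

    def test_annotated_db_from_known_cds(self):
        contigs, cds = _single_cds_genome("ATGAAACGTTAA")
        cfg = pg.DigestConfig(missed_cleavages=0, min_len=1, max_len=50)
        db = pg.build_annotated_db(contigs, cds, cfg)
        # protein MKR digests to MK + R
        assert set(db.entries) == {"MK", "R"}

    def test_minus_strand_cds_yields_identical_peptides(self):
        cfg = pg.DigestConfig(missed_cleavages=0, min_len=1, max_len=50)
        fwd_contigs, fwd_cds = _single_cds_genome("ATGAAACGTTAA", "+")
        rev_contigs, rev_cds = _single_cds_genome("ATGAAACGTTAA", "-")
        a = pg.build_annotated_db(fwd_contigs, fwd_cds, cfg)
        b = pg.build_annotated_db(rev_contigs, rev_cds, cfg)
        assert set(a.entries) == set(b.entries)

    def test_internal_stop_names_the_cds(self):
        contigs, cds = _single_cds_genome("ATGTAAAAATAA")
        with pytest.raises(ValueError, match="g1"):
            pg.build_annotated_db(contigs, cds)

    def test_read_equal_to_full_cds_contains_annotated_peptides(self):
        coding = "ATGAAACGTCTGGATAAACGTTAA"
        contigs, cds = _single_cds_genome(coding)
        cfg = pg.DigestConfig(missed_cleavages=1, min_len=2, max_len=30)
        annotated = pg.build_annotated_db(contigs, cds, cfg)
        naive = pg.build_naive_db(ReadSet([Read("r1", coding)]), cfg)
        assert set(annotated.entries) <= set(naive.entries)


class TestClassifyPeptides:
    def _dbs(self, collapse=True):
        cfg = pg.DigestConfig(collapse_il=collapse)
        naive = pg.PeptideDB(pg.NAIVE, cfg)
        annotated = pg.PeptideDB(pg.ANNOTATED, cfg)
        return cfg, naive, annotated

    def test_partition_and_precedence(self):
        _, naive, annotated = self._dbs()
        naive.add("PEPTIDEK", ("e1", 0))
        naive.add("NAIVEONLYK", ("e2", 0))
        annotated.add("PEPTIDEK", ("g1", 0))
        obs = [
            ObservedPeptide("o1", "PEPTIDEK", 1.0),
            ObservedPeptide("o2", "NAIVEONLYK", 2.0),
            ObservedPeptide("o3", "ABSENTK", 3.0),
        ]
        rep = pg.classify_peptides(obs, naive, annotated)
        assert rep.labels == {
            "o1": "annotated", "o2": "naive_unique", "o3": "unmatched",
        }
        assert rep.n_annotated + rep.n_naive_unique + rep.n_unmatched == len(obs)

    def test_il_collapse_controls_matching(self):
        for collapse, expected in [(True, "annotated"), (False, "unmatched")]:
            cfg, naive, annotated = self._dbs(collapse)
            annotated.add("PEPTIDE", ("g1", 0))
            rep = pg.classify_peptides(
                [ObservedPeptide("o1", "PEPTLDE", 1.0)], naive, annotated
            )
            assert rep.labels["o1"] == expected

    def test_config_mismatch_is_an_error(self):
        naive = pg.PeptideDB(pg.NAIVE, pg.DigestConfig(min_len=6))
        annotated = pg.PeptideDB(pg.ANNOTATED, pg.DigestConfig(min_len=7))
        with pytest.raises(ValueError, match="config"):
            pg.classify_peptides([], naive, annotated)


class TestHydrophobicity:
    def test_single_residue_and_additivity(self):
        assert pg.hydrophobicity("W") == pytest.approx(11.0)
        a, b = "PEPTK", "WLR"
        assert pg.hydrophobicity(a + b) == pytest.approx(
            pg.hydrophobicity(a) + pg.hydrophobicity(b)
        )

    def test_zero_table(self):
        table = {a: 0.0 for a in "ACDEFGHIKLMNPQRSTVWY"}
        assert pg.hydrophobicity("PEPTWK", table) == 0.0

    def test_unknown_residue_and_empty_are_errors(self):
        with pytest.raises(ValueError):
            pg.hydrophobicity("PEPTXDE")
        with pytest.raises(ValueError):
            pg.hydrophobicity("")


class TestFitRetention:
    def _linear_obs(self, n=20, slope=1.5, intercept=4.0):
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        obs = []
        for i in range(n):
            seq = "".join(rng.choice(aas, size=10))
            h = pg.hydrophobicity(seq)
            obs.append(ObservedPeptide(f"o{i}", seq, slope * h + intercept))
        return obs

    def test_noiseless_fit_is_perfect(self):
        fit = pg.fit_retention(self._linear_obs())
        assert fit.correlation == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(4.0)
        assert fit.n_outliers == 0

    def test_gross_outlier_is_the_only_flag(self):
        obs = self._linear_obs(30)
        rng = np.random.default_rng(1)
        # mild noise so residual SD is finite, then one gross outlier
        obs = [
            ObservedPeptide(o.id, o.sequence, o.retention_time + rng.normal(0, 0.1))
            for o in obs
        ]
        obs[7] = ObservedPeptide(
            obs[7].id, obs[7].sequence, obs[7].retention_time + 50.0
        )
        fit = pg.fit_retention(obs)
        assert fit.flags[obs[7].id] == pg.OUTLIER
        assert fit.n_outliers == 1

    def test_too_few_points_is_an_error(self):
        with pytest.raises(ValueError):
            pg.fit_retention(self._linear_obs(2))

    def test_zero_hydrophobicity_variance_is_an_error(self):
        obs = [ObservedPeptide(f"o{i}", "PEPTK", float(i)) for i in range(5)]
        with pytest.raises(ValueError, match="variance"):
            pg.fit_retention(obs)


class TestMapPeptideToGenome:
    def test_peptide_at_contig_start(self):
        contigs = ContigSet([Contig("c1", "ATGAAAGGGCCCTTT")])
        loci = pg.map_peptide_to_genome("MK", contigs)
        assert pg.PeptideLocus("c1", 0, 6, "+", 1) in loci

    def test_absent_peptide_maps_nowhere(self):
        contigs = ContigSet([Contig("c1", "ATGAAAGGGCCCTTT")])
        assert pg.map_peptide_to_genome("WWWWW", contigs) == []

    def test_minus_strand_plant_is_found_on_minus(self):
        from Bio.Seq import Seq

        coding = "ATGAAACGTCTGGAT"  # MKRLD
        seq = "GGGCCC" + str(Seq(coding).reverse_complement()) + "GGGCCC"
        contigs = ContigSet([Contig("c1", seq)])
        loci = pg.map_peptide_to_genome("MKRLD", contigs)
        assert any(
            l.strand == "-" and l.start == 6 and l.end == 6 + len(coding)
            for l in loci
        )

    def test_agrees_with_exhaustive_scan_oracle(self, small_genome):
        """Every locus reported must re-translate to the peptide, and an
        independent brute-force scan over all positions finds the same set."""
        from Bio.Seq import Seq

        _, contigs, truth = small_genome
        cds = next(iter(truth))
        protein = pg.translate_cds(contigs, cds)
        peptide = protein[3:11]
        loci = set(pg.map_peptide_to_genome(peptide, contigs, collapse_il=False))
        # oracle: slide over every nt offset of both strands of every contig
        expected = set()
        for contig in contigs:
            for strand, src in (("+", contig.seq),
                                ("-", str(Seq(contig.seq).reverse_complement()))):
                for off in range(len(src) - 3 * len(peptide) + 1):
                    window = src[off : off + 3 * len(peptide)]
                    if pg.translate(window) == peptide:
                        frame = off % 3 + 1
                        if strand == "+":
                            expected.add(
                                pg.PeptideLocus(contig.id, off,
                                                off + 3 * len(peptide), "+", frame)
                            )
                        else:
                            L = len(src)
                            expected.add(
                                pg.PeptideLocus(contig.id, L - off - 3 * len(peptide),
                                                L - off, "-", -frame)
                            )
        assert loci == expected


class TestAdjudicateAnomalies:
    def _setup(self, n_support):
        obs = [
            ObservedPeptide(f"o{i}", f"PEPTLDEK{'A' * i}", 1.0) for i in range(4)
        ]
        report = pg.MatchReport(
            labels={o.id: pg.LABEL_NAIVE_UNIQUE for o in obs},
            n_annotated=0, n_naive_unique=len(obs), n_unmatched=0,
        )
        fit = pg.RetentionFit(1, 0, 1, 1, {o.id: pg.CONCORDANT for o in obs})
        anomaly = AnomalyRecord("a1", "missing_gene", "c1", 100, 400, "+")
        loci = {
            o.id: [pg.PeptideLocus("c1", 150 + 10 * i, 180 + 10 * i, "+", 1)]
            for i, o in enumerate(obs[:n_support])
        }
        return report, fit, loci, obs, [anomaly]

    def test_enough_concordant_peptides_support(self):
        calls = pg.adjudicate_anomalies(*self._setup(3), min_support=2)
        assert calls[0].verdict == pg.SUPPORTED
        assert len(calls[0].supporting_peptides) == 3

    def test_no_overlapping_peptides_is_no_evidence(self):
        calls = pg.adjudicate_anomalies(*self._setup(0), min_support=2)
        assert calls[0].verdict == pg.NO_EVIDENCE

    def test_wrong_strand_does_not_support(self):
        report, fit, loci, obs, anomalies = self._setup(3)
        flipped = {
            k: [pg.PeptideLocus(l.contig, l.start, l.end, "-", -1) for l in v]
            for k, v in loci.items()
        }
        calls = pg.adjudicate_anomalies(report, fit, flipped, obs, anomalies, 2)
        assert calls[0].verdict == pg.NO_EVIDENCE

    def test_discordant_peptides_do_not_support(self):
        report, fit, loci, obs, anomalies = self._setup(3)
        fit = pg.RetentionFit(1, 0, 1, 1, {o.id: pg.OUTLIER for o in obs})
        calls = pg.adjudicate_anomalies(report, fit, loci, obs, anomalies, 2)
        assert calls[0].verdict == pg.NO_EVIDENCE
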