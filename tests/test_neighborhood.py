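import numpy as np
import pytest

from tierminer import neighborhood as nb
from tierminer.formats_io import AnnotationVote, GeneFeature
from tierminer.synthetic_data import revcomp


def _vote(annotator, annotation, evalue=None, gene="g1"):
    from tierminer.formats_io import normalize_label

    return AnnotationVote(gene, annotator, normalize_label(annotation), evalue)


class TestConsensusAnnotation:
    def test_two_agree(self):
        votes = [
            _vote("dram", "Transposase"),
            _vote("rast", "transposase"),
            _vote("kegg", "hypothetical"),
        ]
        ann = nb.consensus_annotation(votes)
        assert (ann.label, ann.status) == ("transposase", "consensus")

    def test_homology_fallback(self):
        votes = [
            _vote("dram", "helicase"),
            _vote("rast", "permease"),
            _vote("blastp", "integrase", evalue=1e-10),
        ]
        ann = nb.consensus_annotation(votes)
        assert (ann.label, ann.status) == ("putative integrase", "putative")

    def test_fallback_gated_by_evalue(self):
        votes = [
            _vote("dram", "helicase"),
            _vote("blastp", "integrase", evalue=1e-3),
        ]
        ann = nb.consensus_annotation(votes)
        assert ann.status == "hypothetical"

    def test_no_votes(self):
        ann = nb.consensus_annotation([], gene_id="g9")
        assert (ann.gene_id, ann.label, ann.status) == ("g9", "hypothetical", "hypothetical")

    def test_homology_lowest_evalue_nonsentinel_wins(self):
        votes = [
            _vote("blastp", "hypothetical", evalue=1e-40),
            _vote("blastp", "permease", evalue=1e-20),
            _vote("blastp", "kinase", evalue=1e-10),
        ]
        ann = nb.consensus_annotation(votes)
        assert ann.label == "putative permease"

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        votes = [
            _vote("dram", "helicase"),
            _vote("rast", "permease"),
            _vote("kegg", "permease"),
            _vote("blastp", "integrase", evalue=1e-10),
        ]
        base = nb.consensus_annotation(votes)
        for _ in range(10):
            shuffled = [votes[i] for i in rng.permutation(len(votes))]
            assert nb.consensus_annotation(shuffled) == base


class TestOperonOrder:
    def _features(self, roles, strand="+"):
        feats, labels = [], {}
        pos = 1
        for i, role in enumerate(roles):
            gid = f"g{i}"
            feats.append(GeneFeature("c1", gid, pos, pos + 299, strand, gid))
            labels[gid] = role
            pos += 400
        return feats, labels

    def test_correct_order_conforms(self):
        feats, labels = self._features(["alpha", "reductase", "beta", "coupling"])
        assert nb.check_operon_order(feats, labels).conforms is True

    def test_swapped_order_fails(self):
        feats, labels = self._features(["alpha", "beta", "reductase", "coupling"])
        assert nb.check_operon_order(feats, labels).conforms is False

    def test_partial_contig_not_applicable(self):
        feats, labels = self._features(["alpha", "reductase"])
        check = nb.check_operon_order(feats, labels)
        assert check.conforms is None
        assert check.missing == ["beta", "coupling"]

    def test_reverse_strand_read_right_to_left(self):
        feats, labels = self._features(
            ["coupling", "beta", "reductase", "alpha"], strand="-"
        )
        assert nb.check_operon_order(feats, labels).conforms is True

    def test_duplicate_subunit_flagged(self):
        feats, labels = self._features(["alpha", "alpha", "beta", "coupling"])
        check = nb.check_operon_order(feats, labels)
        assert check.conforms is False
        assert check.duplicated == ["alpha"]

    def test_revcomp_contig_same_verdict(self):
        feats, labels = self._features(["alpha", "reductase", "beta", "coupling"])
        contig_len = 2000
        flipped = [
            GeneFeature(
                f.contig_id, f.gene_id,
                contig_len - f.end + 1, contig_len - f.start + 1,
                "-" if f.strand == "+" else "+", f.product_id,
            )
            for f in feats
        ]
        assert (
            nb.check_operon_order(flipped, labels).conforms
            == nb.check_operon_order(feats, labels).conforms
        )


class TestFindItr:
    def test_terminal_revcomp_gene_pair(self, rng):
        gene = "".join(rng.choice(list("ACGT"), size=240))
        middle = "".join(rng.choice(list("ACGT"), size=600))
        contig = gene + middle + revcomp(gene)
        feats = [
            GeneFeature("c1", "g1", 1, 240, "+", "g1"),
            GeneFeature("c1", "gmid", 300, 500, "+", "gmid"),
            GeneFeature("c1", "gN", 841, 1080, "-", "gN"),
        ]
        findings = nb.find_itr(contig, feats)
        kinds = {f.kind for f in findings}
        assert "gene_pair" in kinds
        gp = next(f for f in findings if f.kind == "gene_pair")
        assert (gp.first_id, gp.last_id, gp.length_bp) == ("g1", "gN", 240)

    def test_no_repeats_empty(self, rng):
        contig = "".join(rng.choice(list("ACGT"), size=1000))
        feats = [GeneFeature("c1", "g1", 1, 200, "+", "g1"),
                 GeneFeature("c1", "g2", 700, 1000, "+", "g2")]
        assert nb.find_itr(contig, feats) == []


class TestTerminalOverlaps:
    def brute_force(self, a, b, min_len):
        """All-offsets quadratic oracle for one unordered pair."""
        out = set()
        combos = [
            (a, b, "3'", "5'"),
            (b, a, "5'", "3'"),
            (a, revcomp(b), "3'", "3'"),
            (revcomp(b), a, "5'", "5'"),
        ]
        for x, y, a_end, b_end in combos:
            best = 0
            for L in range(min_len, min(len(x), len(y)) + 1):
                if x[len(x) - L :] == y[:L]:
                    best = L
            if best:
                out.add((a_end, b_end, best))
        return out

    def test_planted_127bp_overlap(self, rng):
        shared = "".join(rng.choice(list("ACGT"), size=127))
        a = "".join(rng.choice(list("ACGT"), size=800)) + shared
        b = shared + "".join(rng.choice(list("ACGT"), size=600))
        findings = nb.find_terminal_overlaps([("a", a), ("b", b)], min_len=100)
        assert any(
            (f.a_end, f.b_end, f.length_bp) == ("3'", "5'", 127) for f in findings
        )

    def test_short_overlap_below_min_len(self, rng):
        shared = "".join(rng.choice(list("ACGT"), size=50))
        a = "".join(rng.choice(list("ACGT"), size=500)) + shared
        b = shared + "".join(rng.choice(list("ACGT"), size=500))
        assert nb.find_terminal_overlaps([("a", a), ("b", b)], min_len=100) == []

    def test_revcomp_join_detected(self, rng):
        shared = "".join(rng.choice(list("ACGT"), size=150))
        a = "".join(rng.choice(list("ACGT"), size=400)) + shared
        b = "".join(rng.choice(list("ACGT"), size=400)) + revcomp(shared)
        findings = nb.find_terminal_overlaps([("a", a), ("b", b)], min_len=100)
        assert any(
            (f.a_end, f.b_end) == ("3'", "3'") and f.length_bp >= 150 for f in findings
        )

    def test_agrees_with_quadratic_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(8):
            n1 = int(rng.integers(200, 2000))
            n2 = int(rng.integers(200, 2000))
            a = "".join(rng.choice(list("ACGT"), size=n1))
            b = "".join(rng.choice(list("ACGT"), size=n2))
            if trial % 2 == 0:  # plant an overlap half the time
                L = int(rng.integers(100, 180))
                b = a[-L:] + b[L:]
            got = {
                (f.a_end, f.b_end, f.length_bp)
                for f in nb.find_terminal_overlaps([("a", a), ("b", b)], min_len=100)
            }
            assert got == self.brute_force(a, b, 100), f"trial {trial}"

    def test_mismatch_tolerance_not_implemented(self):
        with pytest.raises(NotImplementedError):
            nb.find_terminal_overlaps([("a", "ACGT"), ("b", "ACGT")], max_mismatch=1)

    def test_needs_two_contigs(self):
        with pytest.raises(ValueError):
            nb.find_terminal_overlaps([("a", "ACGT")])
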