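"""Degenerate-primer matching, in-silico PCR and amplifiability audits."""

import numpy as np
import pytest

from lignoamp.primers import (
    DegeneratePrimer,
    GeneModel,
    PrimerPair,
    amplifiable_fraction,
    degeneracy,
    evaluate_amplifiability,
    find_binding_sites,
    in_silico_pcr,
    match_window,
    revcomp,
)
from lignoamp.simulate import simulate_gene_models

from conftest import mutate


def _primer(seq, orientation="forward", family="GH5-5"):
    return DegeneratePrimer("p", seq, orientation, family)


GH55_F = "GARATGCAYCARTACCTYGA"
GH55_R = "CANGGICCRGCRGCCCACCA"
GH11_F = "GGVAAGGGITGGAAYCCNGG"


class TestDegeneracy:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGT", 1),
            (GH55_F, 16),  # R,Y,R,Y -> 2*2*2*2, matches brute-force expansion
            (GH11_F, 96),  # V,I,Y,N -> 3*4*2*4
        ],
    )
    def test_known_counts(self, seq, expected):
        assert degeneracy(_primer(seq)) == expected

    def test_equals_bruteforce_expansion_count(self):
        primer = _primer(GH55_F)
        assert degeneracy(primer) == len(set(primer.expansions()))

    def test_multiplicative_over_concatenation(self):
        rng = np.random.default_rng(0)
        symbols = list("ACGTRYSWKMBDHVNI")
        for _ in range(20):
            a = "".join(rng.choice(symbols, 6))
            b = "".join(rng.choice(symbols, 5))
            assert degeneracy(a + b) == degeneracy(a) * degeneracy(b)

    def test_invalid_symbol_named_in_error(self):
        with pytest.raises(ValueError, match="'X'"):
            degeneracy("ACXG")


class TestMatchWindow:
    def test_expansion_member_is_exact_match(self):
        assert match_window(_primer(GH55_F), "GAAATGCATCAATACCTTGA") == 0

    def test_single_code_violation(self):
        # third base C is outside R = {A, G}
        assert match_window(_primer(GH55_F), "GACATGCATCAATACCTTGA") == 1

    def test_window_n_only_matches_primer_wildcards(self):
        assert match_window(_primer("ANIA"), "ANNA") == 0
        assert match_window(_primer("AAAA"), "ANAA") == 1

    def test_length_contract(self):
        with pytest.raises(ValueError):
            match_window(_primer("ACGT"), "ACG")

    def test_enumeration_oracle(self):
        """Mismatch count equals the per-position-membership minimum Hamming
        distance to the explicit expansion set (N-free windows)."""
        rng = np.random.default_rng(1)
        primer = _primer("ARYGTNAC")  # degeneracy 2*2*4 = 16... small enough
        expansions = list(primer.expansions())
        for _ in range(50):
            window = "".join(rng.choice(list("ACGT"), len(primer.sequence)))
            oracle = min(
                sum(a != b for a, b in zip(window, exp)) for exp in expansions
            )
            assert match_window(primer, window) == oracle
            assert (match_window(primer, window) == 0) == (window in expansions)


class TestBindingSites:
    def _template(self, rng, n=300):
        return "".join(rng.choice(list("ACGT"), n))

    def test_planted_forward_site(self):
        rng = np.random.default_rng(2)
        site = "GAAATGCATCAATACCTTGA"
        template = self._template(rng, 10) + site + self._template(rng, 50)
        hits = find_binding_sites(template, _primer(GH55_F), max_mm=0)
        plus = [h for h in hits if h.strand == "+"]
        assert [(h.start, h.mismatches) for h in plus] == [(10, 0)]

    def test_strand_symmetry(self):
        rng = np.random.default_rng(3)
        site = "GAAATGCATCAATACCTTGA"
        template = self._template(rng, 10) + site + self._template(rng, 50)
        hits = find_binding_sites(revcomp(template), _primer(GH55_F), max_mm=0)
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        assert minus[0].start == len(template) - 30

    def test_no_site_matches_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        primer = _primer(GH55_F)
        template = self._template(rng, 400)
        hits = find_binding_sites(template, primer, max_mm=2)
        # exhaustive window-scan oracle over both strands
        oracle = []
        for strand, pattern in (("+", primer.sequence), ("-", revcomp(primer.sequence))):
            for i in range(len(template) - len(primer) + 1):
                mm = match_window(pattern, template[i : i + len(primer)])
                if mm <= 2:
                    oracle.append((i, strand, mm))
        assert [(h.start, h.strand, h.mismatches) for h in hits] == sorted(oracle)


class TestInSilicoPcr:
    @pytest.fixture()
    def gh55_template(self, primer_pairs):
        pair = primer_pairs["GH5-5"]
        rng = np.random.default_rng(5)
        from lignoamp.primers import IUPAC_SETS

        fwd = "".join(sorted(IUPAC_SETS[c])[0] for c in pair.fwd.sequence)
        rev = "".join(sorted(IUPAC_SETS[c])[0] for c in pair.rev.sequence)
        insert_len = pair.expected_product_length - len(fwd) - len(rev)
        insert = "".join(rng.choice(list("ACGT"), insert_len))
        amplicon = fwd + insert + revcomp(rev)
        left = "".join(rng.choice(list("ACGT"), 350))
        right = "".join(rng.choice(list("ACGT"), 350))
        return pair, left + amplicon + right, amplicon

    def test_planted_product_of_expected_length(self, gh55_template):
        pair, template, amplicon = gh55_template
        products = in_silico_pcr(template, pair, max_mm=2)
        assert len(products) == 1
        assert len(products[0]) == 248
        assert products[0].sequence == amplicon

    def test_missing_reverse_site_gives_nothing(self, gh55_template):
        pair, template, amplicon = gh55_template
        truncated = template[: template.index(amplicon) + 100]
        assert in_silico_pcr(truncated, pair, max_mm=2) == []

    def test_two_forward_sites_give_two_products(self, gh55_template):
        pair, template, amplicon = gh55_template
        fwd_footprint = amplicon[: len(pair.fwd)]
        idx = template.index(amplicon)
        doubled = (
            template[: idx - 60] + fwd_footprint + template[idx - 40 : ]
        )
        products = in_silico_pcr(doubled, pair, max_mm=2, min_len=100, max_len=400)
        assert len(products) == 2
        assert products[0].start < products[1].start

    def test_strand_symmetry(self, gh55_template):
        pair, template, _ = gh55_template
        fwd_products = in_silico_pcr(template, pair, max_mm=2)
        rc_products = in_silico_pcr(revcomp(template), pair, max_mm=2)
        assert sorted(p.sequence for p in fwd_products) == sorted(
            p.sequence for p in rc_products
        )
        assert {p.strand for p in rc_products} == {"-"}

    def test_monotone_in_mismatch_allowance(self, gh55_template):
        pair, template, _ = gh55_template
        mutated = mutate(template, [360, 365])  # inside the fwd footprint region
        previous: set = set()
        for k in range(4):
            current = {p.sequence for p in in_silico_pcr(mutated, pair, max_mm=k)}
            assert previous <= current
            previous = current


class TestAmplifiability:
    @pytest.fixture()
    def planted_genes(self, primer_pairs):
        statuses = [
            "amplifiable", "amplifiable", "intron_disrupted",
            "divergent_site", "no_product",
        ]
        genes, truth = simulate_gene_models(primer_pairs["GH11"], statuses, seed=11)
        return primer_pairs["GH11"], genes, truth

    def test_verdicts_match_planted_truth(self, planted_genes):
        pair, genes, truth = planted_genes
        for gene, expected in zip(genes, truth):
            assert evaluate_amplifiability(gene, pair).status == expected

    def test_fraction_is_exact(self, planted_genes):
        pair, genes, _ = planted_genes
        fraction, verdicts = amplifiable_fraction(genes, pair)
        assert fraction == pytest.approx(2 / 5)
        assert len(verdicts) == 5

    def test_single_exon_gene_with_exact_sites(self, primer_pairs):
        pair = primer_pairs["GH11"]
        genes, _ = simulate_gene_models(pair, ["amplifiable"], seed=12)
        verdict = evaluate_amplifiability(genes[0], pair)
        assert verdict.status == "amplifiable"
        assert verdict.fwd_mismatches == 0 and verdict.rev_mismatches == 0
        assert verdict.product_length == pair.expected_product_length

    def test_empty_gene_list_rejected(self, primer_pairs):
        with pytest.raises(ValueError):
            amplifiable_fraction([], primer_pairs["GH11"])

    def test_malformed_exons_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "ACGT" * 10, ((0, 10), (5, 20)))


class TestBundleInvariants:
    def test_product_lengths_exceed_primer_lengths(self, primer_pairs):
        for pair in primer_pairs.values():
            assert pair.expected_product_length > len(pair.fwd) + len(pair.rev)

    def test_expected_lengths(self, primer_pairs):
        lengths = {f: p.expected_product_length for f, p in primer_pairs.items()}
        assert lengths == {"GH7": 515, "GH5-5": 248, "GH11": 281, "AA2": 398}
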