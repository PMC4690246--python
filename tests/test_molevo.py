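import itertools

import numpy as np
import pytest

from straindiff import molevo
from straindiff.config import AnalysisConfig
from straindiff.io import ValidationError

CODE = molevo._CODON_TABLE
STOPS = molevo._STOPS
SENSE = sorted(CODE)


def oracle_sites(codon):
    """Independent per-codon site counter (stop-producing changes count as
    nonsynonymous)."""
    syn = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if CODE.get(alt) == CODE[codon]:
                syn += 1 / 3
    return syn, 3 - syn


def oracle_differences(c1, c2):
    """Brute-force pathway enumeration; stop-passing paths excluded."""
    pos = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(pos):
        cur, sd, nd, ok = c1, 0, 0, True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in STOPS and nxt != c2 and len(pos) > 1:
                ok = False
                break
            if CODE.get(cur) == CODE.get(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        for order in itertools.permutations(pos):
            cur, sd, nd = c1, 0, 0
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1:]
                sd += CODE.get(cur) == CODE.get(nxt)
                nd += CODE.get(cur) != CODE.get(nxt)
                cur = nxt
            results.append((sd, nd))
    return (float(np.mean([r[0] for r in results])),
            float(np.mean([r[1] for r in results])))


class TestKaKs:
    def test_identical_sequences(self):
        ka, ks, ratio, sat = molevo.compute_ka_ks("AAATTTGGG", "AAATTTGGG")
        assert ka == 0 and ks == 0 and ratio is None and not sat

    def test_hand_enumerated_example(self):
        """AAA TTT GGG vs AAA TTC GGG: S=5/3 per sequence, one synonymous
        difference, ps=0.6, Ks = -0.75 ln(0.2)."""
        ka, ks, ratio, sat = molevo.compute_ka_ks("AAATTTGGG", "AAATTCGGG")
        assert ka == 0.0
        assert ks == pytest.approx(-0.75 * np.log(0.2), rel=1e-12)
        assert ratio == 0.0

    def test_symmetry(self, rng):
        a = "".join(rng.choice(SENSE, 40))
        b = "".join(rng.choice(SENSE, 40))
        assert molevo.compute_ka_ks(a, b) == molevo.compute_ka_ks(b, a)

    def test_fourfold_only_mutations_give_ka_zero(self, rng):
        """Mutating only 4-fold-degenerate third positions: Ka = 0 exactly."""
        fourfold = [c for c in SENSE
                    if len({CODE.get(c[:2] + n) for n in "ACGT"}) == 1
                    and all(c[:2] + n in CODE for n in "ACGT")]
        codons = list(rng.choice(fourfold, 60))
        mutated = list(codons)
        for i in range(0, 60, 3):
            c = mutated[i]
            alt = [n for n in "ACGT" if n != c[2]]
            mutated[i] = c[:2] + alt[0]
        ka, ks, _, _ = molevo.compute_ka_ks("".join(codons), "".join(mutated))
        assert ka == 0.0 and ks > 0

    def test_site_counts_match_oracle_all_codons(self):
        for codon in SENSE:
            assert molevo._codon_sites(codon) == pytest.approx(
                oracle_sites(codon))

    def test_pathway_counts_match_oracle_two_diff_pairs(self):
        """All sense-codon pairs with <= 2 differences agree with the
        brute-force enumerator."""
        for c1 in SENSE:
            for c2 in SENSE:
                ndiff = sum(a != b for a, b in zip(c1, c2))
                if 0 < ndiff <= 2:
                    assert molevo._codon_differences(c1, c2) == pytest.approx(
                        oracle_differences(c1, c2)), (c1, c2)

    def test_against_biopython_ng86(self, rng):
        """Independent NG86 implementation agrees on clean random pairs."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        for seed in range(5):
            r = np.random.default_rng(seed)
            codons = list(r.choice(SENSE, 120))
            mutated = list(codons)
            for i in r.choice(120, 15, replace=False):
                c = mutated[int(i)]
                alts = [c[:2] + n for n in "ACGT"
                        if n != c[2] and c[:2] + n in CODE]
                if alts:
                    mutated[int(i)] = alts[0]
            a, b = "".join(codons), "".join(mutated)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            ka, ks, _, _ = molevo.compute_ka_ks(a, b)
            assert ka == pytest.approx(dn, abs=5e-3)
            assert ks == pytest.approx(ds, abs=5e-3)

    def test_saturation_flag(self):
        """ps >= 0.75 returns the raw proportion flagged as saturated."""
        a = "TTA" * 50
        b = "CTG" * 50  # same aa (Leu), two syn differences per codon
        ka, ks, _, sat = molevo.compute_ka_ks(a, b)
        assert sat and ka == 0.0

    def test_length_contract(self):
        with pytest.raises(ValidationError):
            molevo.compute_ka_ks("AAA", "AAAAAA")
        with pytest.raises(ValidationError):
            molevo.compute_ka_ks("AAAA", "AAAT")

    def test_ambiguous_codons_excluded_pairwise(self):
        ka1 = molevo.compute_ka_ks("AAATTT", "AAATTC")
        ka2 = molevo.compute_ka_ks("AAANNNTTT", "AAAGGGTTC")
        assert ka1[1] == pytest.approx(ka2[1])


class TestRateClass:
    @pytest.mark.parametrize("ratio,expected", [
        (0.5, "conserved"), (0.7499, "conserved"), (0.75, "neutral"),
        (1.0, "neutral"), (1.2499, "neutral"), (1.25, "rapid"),
        (1.3, "rapid"), (None, "undefined"),
    ])
    def test_thresholds(self, config, ratio, expected):
        assert molevo.rate_class(ratio, config) == expected


class TestStructuralCascade:
    def _aln(self, **kw):
        base = dict(gene_id="g", coverage=1.0, target_cds="ATGAAATAA",
                    has_start=True, frameshift=False, premature_stop=False,
                    stop_lost=False, protein_identical=True)
        base.update(kw)
        return molevo.OrthologAlignment(**base)

    def test_low_coverage_no_ortholog(self):
        aln = self._aln(coverage=0.5)
        assert molevo.classify_ortholog_pair(aln, 3) == "no_ortholog"

    def test_no_start_orf_not_detected(self):
        aln = self._aln(has_start=False)
        assert molevo.classify_ortholog_pair(aln, 3) == "orf_not_detected"

    def test_frameshift_different_length(self):
        aln = self._aln(frameshift=True)
        assert molevo.classify_ortholog_pair(aln, 3) == "different_protein_length"

    def test_substitution_vs_identical(self):
        assert molevo.classify_ortholog_pair(
            self._aln(protein_identical=False), 3) == "amino_acid_substitution"
        assert molevo.classify_ortholog_pair(
            self._aln(protein_identical=True), 3) == "same_protein_sequence"

    def test_one_bp_deletion_detected_from_sequences(self):
        a = "ATG" + "AAATTTGGGCCC" * 10 + "TAA"
        b = a[:20] + a[21:]  # 1-bp deletion mid-CDS
        aln = molevo.pair_alignment("g", a, b)
        assert aln.frameshift
        prot_len = len(a) // 3
        assert molevo.classify_ortholog_pair(aln, prot_len) == \
            "different_protein_length"

    def test_single_residue_substitution(self):
        a = "ATG" + "AAA" * 30 + "TAA"
        b = "ATG" + "AAA" * 15 + "CGA" + "AAA" * 14 + "TAA"
        aln = molevo.pair_alignment("g", a, b)
        assert molevo.classify_ortholog_pair(aln, len(a) // 3) == \
            "amino_acid_substitution"


class TestSummarize:
    def test_partition_enforced(self, config):
        import pandas as pd
        ev = pd.DataFrame({"gene_id": ["g1", "g1"],
                           "structural_class": ["same_protein_sequence"] * 2,
                           "rate_class": ["undefined"] * 2})
        with pytest.raises(ValidationError):
            molevo.summarize_evolution(ev, {"g1": "SE"})

    def test_counts_and_classes(self, config):
        import pandas as pd
        ev = pd.DataFrame({
            "gene_id": ["g1", "g2", "g3"],
            "structural_class": ["no_ortholog", "same_protein_sequence",
                                 "no_ortholog"],
            "rate_class": ["undefined", "conserved", "undefined"]})
        struct, rates = molevo.summarize_evolution(
            ev, {"g1": "global", "g2": "SE", "g3": "global"})
        assert struct.loc["no_ortholog", "global"] == 2
        assert rates.loc["conserved", "SE"] == 1
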