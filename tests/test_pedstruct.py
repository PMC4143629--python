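"""Pedigree parsing and relationship-matrix construction."""

import numpy as np
import pytest

from pedscore._errors import ConfigurationError, CycleError, ValidationError
from pedscore.pedstruct import (
    Pedigree,
    RelationshipMatrix,
    delta7_matrix,
    household_matrix,
    kinship_matrix,
    read_pedigree,
)
from pedscore.simkit import gene_drop_alleles, random_pedigree


def write(path, text):
    path.write_text(text)
    return path


class TestReadPedigree:
    def test_trio_csv(self, tmp_path):
        p = write(tmp_path / "ped.csv",
                  "family,person,father,mother,sex\n"
                  "f1,F,,,male\nf1,M,,,female\nf1,C,F,M,female\n")
        ped = read_pedigree(p, "csv")
        assert ped.n == 3
        assert len(ped.founders) == 2
        assert [ped.individuals[i].person for i in ped.order] == ["F", "M", "C"]

    def test_plink_fam_dialect(self, tmp_path):
        p = write(tmp_path / "ped.fam",
                  "f1 F 0 0 1 -9\nf1 M 0 0 2 -9\nf1 C F M 2 -9\n")
        ped = read_pedigree(p, "plink_fam")
        assert ped.n == 3
        child = ped.individuals[2]
        assert (child.father, child.mother, child.sex) == ("F", "M", "female")

    def test_child_listed_before_parents_reorders(self, tmp_path):
        p = write(tmp_path / "ped.csv",
                  "family,person,father,mother,sex\n"
                  "f1,C,F,M,female\nf1,F,,,male\nf1,M,,,female\n")
        ped = read_pedigree(p, "csv")
        topo = [ped.individuals[i].person for i in ped.order]
        assert topo.index("C") > topo.index("F")
        assert topo.index("C") > topo.index("M")
        # same kinship as a well-ordered file, up to the permutation
        phi = kinship_matrix(ped)
        assert phi.values[phi.ids.index("C"), phi.ids.index("F")] == 0.25

    def test_own_grandparent_cycle(self):
        with pytest.raises(CycleError):
            Pedigree.from_records([
                ("f1", "A", "C", "B", "male"),
                ("f1", "B", "", "", "female"),
                ("f1", "C", "A", "D", "male"),
                ("f1", "D", "", "", "female"),
            ])

    def test_single_parent_rejected(self):
        with pytest.raises(ValidationError, match="one known parent"):
            Pedigree.from_records([("f1", "M", "", "", "female"),
                                   ("f1", "C", "", "M", "male")])

    def test_duplicate_person_rejected(self):
        with pytest.raises(ValidationError, match="duplicated"):
            Pedigree.from_records([("f1", "A", "", "", "male"),
                                   ("f1", "A", "", "", "male")])

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValidationError, match="not found"):
            Pedigree.from_records([("f1", "C", "X", "Y", "male")])


class TestKinship:
    def test_trio_values(self, trio):
        phi = kinship_matrix(trio).values
        assert phi[0, 1] == 0.0          # founders unrelated
        assert phi[0, 2] == phi[1, 2] == 0.25
        assert np.all(np.diag(phi) == 0.5)

    def test_siblings_and_cousins(self, family16):
        phi = kinship_matrix(family16)
        ids = phi.ids
        sib = phi.values[ids.index("fam1_c1k1"), ids.index("fam1_c1k2")]
        cousin = phi.values[ids.index("fam1_c1k1"), ids.index("fam1_c2k1")]
        assert sib == 0.25
        assert cousin == 1 / 16

    def test_child_of_first_cousins_inbred_self_kinship(self):
        # grandparents -> two sibs -> first cousins -> their child
        ped = Pedigree.from_records([
            ("f", "g1", "", "", "male"), ("f", "g2", "", "", "female"),
            ("f", "p1", "g1", "g2", "male"), ("f", "p2", "g1", "g2", "female"),
            ("f", "s1", "", "", "female"), ("f", "s2", "", "", "male"),
            ("f", "c1", "p1", "s1", "male"), ("f", "c2", "s2", "p2", "female"),
            ("f", "child", "c1", "c2", "male"),
        ])
        phi = kinship_matrix(ped)
        assert phi.values[-1, -1] == pytest.approx(0.5 * (1 + 1 / 16))

    def test_cross_family_zero_and_psd(self, sample160):
        phi = kinship_matrix(sample160)
        # block diagonal across families
        assert phi.values[0, 20] == 0.0
        eig = np.linalg.eigvalsh(2 * phi.values)
        assert eig.min() >= -1e-10

    def test_row_permutation_equivariance(self, family16, rng):
        perm = rng.permutation(family16.n)
        ped_perm = Pedigree([family16.individuals[i] for i in perm])
        phi = kinship_matrix(family16).values
        phi_perm = kinship_matrix(ped_perm).values
        assert np.allclose(phi_perm, phi[np.ix_(perm, perm)])

    def test_gene_drop_oracle_on_random_pedigrees(self, rng):
        """Recursive kinship equals Monte-Carlo IBD frequency within 3 SE."""
        for k in range(3):
            ped = random_pedigree(rng, f"fam{k}")
            phi = kinship_matrix(ped).values
            labels = gene_drop_alleles(ped, rng, size=20000)
            picks_i = rng.integers(0, 2, size=(ped.n, 20000))
            # P(random allele of i IBD random allele of j), est. by one draw each
            a_i = np.take_along_axis(labels.transpose(0, 2, 1),
                                     picks_i[:, :, None], axis=2)[:, :, 0]
            for (i, j) in [(0, ped.n - 1), (ped.n - 2, ped.n - 1), (2, 3)]:
                picks_j = rng.integers(0, 2, size=20000)
                a_j = labels[j, picks_j, np.arange(20000)]
                share = (a_i[i] == a_j).mean()
                se = np.sqrt(max(share * (1 - share), 1e-6) / 20000)
                assert abs(share - phi[i, j]) < max(3 * se, 5e-3)


class TestDelta7:
    def test_full_siblings(self, family16):
        d7 = delta7_matrix(family16)
        ids = d7.ids
        assert d7.values[ids.index("fam1_c1k1"), ids.index("fam1_c1k2")] == 0.25

    def test_parent_offspring_zero(self, trio):
        d7 = delta7_matrix(trio).values
        assert d7[0, 2] == 0.0 and d7[1, 2] == 0.0

    def test_founder_pairs_zero_and_diag_one(self, family16):
        d7 = delta7_matrix(family16).values
        assert d7[0, 1] == 0.0
        assert np.all(np.diag(d7) == 1.0)

    def test_double_first_cousins(self):
        # two sibships intermarry: children share both parents' sibling pairs
        ped = Pedigree.from_records([
            ("f", "a1", "", "", "male"), ("f", "a2", "", "", "female"),
            ("f", "b1", "", "", "male"), ("f", "b2", "", "", "female"),
            ("f", "s1", "a1", "a2", "male"), ("f", "s2", "a1", "a2", "female"),
            ("f", "t1", "b1", "b2", "female"), ("f", "t2", "b1", "b2", "male"),
            ("f", "u", "s1", "t1", "male"), ("f", "v", "t2", "s2", "female"),
        ])
        d7 = delta7_matrix(ped)
        ids = d7.ids
        assert d7.values[ids.index("u"), ids.index("v")] == pytest.approx(1 / 16)

    def test_double_first_cousins_gene_drop_oracle(self, rng):
        ped = Pedigree.from_records([
            ("f", "a1", "", "", "male"), ("f", "a2", "", "", "female"),
            ("f", "b1", "", "", "male"), ("f", "b2", "", "", "female"),
            ("f", "s1", "a1", "a2", "male"), ("f", "s2", "a1", "a2", "female"),
            ("f", "t1", "b1", "b2", "female"), ("f", "t2", "b1", "b2", "male"),
            ("f", "u", "s1", "t1", "male"), ("f", "v", "t2", "s2", "female"),
        ])
        n_drop = 100000
        labels = gene_drop_alleles(ped, rng, size=n_drop)
        u, v = 8, 9
        both = (((labels[u, 0] == labels[v, 0]) & (labels[u, 1] == labels[v, 1]))
                | ((labels[u, 0] == labels[v, 1]) & (labels[u, 1] == labels[v, 0])))
        freq = both.mean()
        se = np.sqrt(freq * (1 - freq) / n_drop)
        assert abs(freq - 1 / 16) < 3 * se

    def test_unrelated_pairs_zero_and_bound(self, sample160):
        phi = kinship_matrix(sample160).values
        d7 = delta7_matrix(sample160).values
        assert np.all(d7[phi == 0] == 0.0)
        off = ~np.eye(sample160.n, dtype=bool)
        assert np.all(d7[off] <= 4 * phi[off] + 1e-12)

    def test_inbred_pedigree_warns(self):
        ped = Pedigree.from_records([
            ("f", "g1", "", "", "male"), ("f", "g2", "", "", "female"),
            ("f", "p1", "g1", "g2", "male"), ("f", "p2", "g1", "g2", "female"),
            ("f", "child", "p1", "p2", "male"),
        ])
        with pytest.warns(UserWarning, match="inbred"):
            delta7_matrix(ped)


class TestHousehold:
    def test_blocks(self):
        ped = Pedigree.from_records([
            ("f", "a", "", "", "male", "h1"),
            ("f", "b", "", "", "female", "h1"),
            ("f", "c", "", "", "male", "h2"),
        ])
        h = household_matrix(ped).values
        assert np.array_equal(h, np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1.0]]))

    def test_all_same_and_all_distinct(self):
        same = Pedigree.from_records([("f", str(i), "", "", "male", "h")
                                      for i in range(4)])
        assert np.all(household_matrix(same).values == 1.0)
        dist = Pedigree.from_records([("f", str(i), "", "", "male", f"h{i}")
                                      for i in range(4)])
        assert np.array_equal(household_matrix(dist).values, np.eye(4))

    def test_missing_household_label_rejected(self, trio):
        with pytest.raises(ConfigurationError, match="household"):
            household_matrix(trio)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.permutations(list(range(16))))
def test_relationship_matrices_permutation_equivariant(perm):
    """Reordering input rows permutes Φ, Δ7 and H consistently."""
    from pedscore.simkit import three_generation_pedigree
    ped = three_generation_pedigree("fam1")
    ped_perm = Pedigree([ped.individuals[i] for i in perm])
    ix = np.ix_(perm, perm)
    assert np.allclose(kinship_matrix(ped_perm).values,
                       kinship_matrix(ped).values[ix])
    assert np.allclose(delta7_matrix(ped_perm).values,
                       delta7_matrix(ped).values[ix])
    assert np.allclose(household_matrix(ped_perm).values,
                       household_matrix(ped).values[ix])


def test_matrix_text_round_trip(tmp_path, family16):
    phi = kinship_matrix(family16)
    path = tmp_path / "phi.txt"
    phi.to_text(path)
    back = RelationshipMatrix.from_text(path)
    assert back.kind == "kinship"
    assert back.ids == phi.ids
    assert np.array_equal(back.values, phi.values)
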