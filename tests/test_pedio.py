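"""Pedigree file I/O, kinship recursion and analysis-sample assembly."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdtpoly import pedio, simulator
from gdtpoly.pedio import FamilySample, Pedigree, PedigreeError

PED_TRIO = """\
1 1 0 0 1 2 1 2
1 2 0 0 2 1 1 1
1 3 1 2 1 2 1 2
"""
DAT_TRIO = "A disease\nM snp1\n"


def write_trio(tmp_path, ped_text=PED_TRIO, dat_text=DAT_TRIO):
    ped = tmp_path / "fam.ped"
    dat = tmp_path / "fam.dat"
    ped.write_text(ped_text)
    dat.write_text(dat_text)
    return ped, dat


class TestReadPedigree:
    def test_trio_parses_and_child_allele_proportion_is_half(self, tmp_path):
        pdata = pedio.read_pedigree(*write_trio(tmp_path))
        fd = pdata.families["1"]
        assert pdata.trait_names == ["disease"] and pdata.marker_names == ["snp1"]
        # affection 2 -> affected (1), 1 -> unaffected (0)
        assert fd.traits["disease"].tolist() == [1.0, 0.0, 1.0]
        prop = pedio.allele_proportions(fd.genotypes["snp1"], "2")
        assert prop[2] == 0.5  # heterozygote "1 2"

    def test_missing_genotype_gives_nan_proportion(self, tmp_path):
        ped = PED_TRIO.replace("1 3 1 2 1 2 1 2", "1 3 1 2 1 2 0 0")
        pdata = pedio.read_pedigree(*write_trio(tmp_path, ped))
        prop = pedio.allele_proportions(
            pdata.families["1"].genotypes["snp1"], "2"
        )
        assert np.isnan(prop[2])

    def test_gzip_input_accepted(self, tmp_path):
        ped = tmp_path / "fam.ped.gz"
        dat = tmp_path / "fam.dat"
        with gzip.open(ped, "wt") as fh:
            fh.write(PED_TRIO)
        dat.write_text(DAT_TRIO)
        pdata = pedio.read_pedigree(ped, dat)
        assert pdata.families["1"].pedigree.n == 3

    @pytest.mark.parametrize(
        "mutation, message",
        [
            (lambda t: t.replace("1 3 1 2", "1 3 9 2"), "unknown parent"),
            (lambda t: t + "1 3 0 0 2 1 1 1\n", "duplicated member"),
            (lambda t: t.replace("1 3 1 2 1 2 1 2\n", "1 3 1 2 1 2 1\n"),
             "columns"),
        ],
    )
    def test_malformed_files_raise_with_context(self, tmp_path, mutation, message):
        with pytest.raises(PedigreeError, match=message):
            pedio.read_pedigree(*write_trio(tmp_path, mutation(PED_TRIO)))

    def test_roundtrip_is_lossless(self, tmp_path, small_sim):
        paths = simulator.write_merlin(small_sim, tmp_path / "sim")
        pdata = pedio.read_pedigree(paths["ped"], paths["dat"])
        pedio.write_pedigree(pdata, tmp_path / "rt.ped", tmp_path / "rt.dat")
        again = pedio.read_pedigree(tmp_path / "rt.ped", tmp_path / "rt.dat")
        assert again.trait_names == pdata.trait_names
        assert again.marker_names == pdata.marker_names
        for fam, fd in pdata.families.items():
            fd2 = again.families[fam]
            assert fd2.pedigree.ids == fd.pedigree.ids
            assert (fd2.pedigree.father == fd.pedigree.father).all()
            for t in pdata.trait_names:
                np.testing.assert_array_equal(fd2.traits[t], fd.traits[t])
            for m in pdata.marker_names:
                np.testing.assert_array_equal(fd2.genotypes[m], fd.genotypes[m])


class TestKinship:
    def test_textbook_relationships(self):
        # grandparent couple, two married children, one grandchild each
        ped = Pedigree(
            "1",
            [str(i) for i in range(1, 9)],
            np.array([-1, -1, 0, 0, -1, -1, 2, 3]),
            np.array([-1, -1, 1, 1, -1, -1, 4, 5]),
            np.ones(8, dtype=int),
        )
        phi = ped.kinship()
        assert phi[0, 2] == pytest.approx(0.25)      # parent-offspring
        assert phi[2, 3] == pytest.approx(0.25)      # full siblings
        assert phi[6, 7] == pytest.approx(0.0625)    # first cousins
        assert phi[0, 1] == 0.0                      # unrelated founders
        assert phi[0, 0] == 0.5

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(PedigreeError, match="cyclic"):
            Pedigree(
                "1", ["1", "2", "3"],
                np.array([2, -1, 0]), np.array([1, -1, 1]),
                np.ones(3, dtype=int),
            )

    def test_single_known_parent_rejected(self):
        with pytest.raises(PedigreeError, match="one known parent"):
            Pedigree(
                "1", ["1", "2"], np.array([-1, 0]), np.array([-1, -1]),
                np.ones(2, dtype=int),
            )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(n_children=st.integers(0, 4), seed=st.integers(0, 10**6))
    def test_kinship_psd_and_sharing_in_range(self, n_children, seed):
        """2*phi is a valid expected-IBD matrix: PSD, off-diagonal in [0,1],
        diagonal in [1,2] — on random multi-generation structures."""
        rng = np.random.default_rng(seed)
        base = simulator.canonical_pedigree()
        keep = sorted(
            set(range(10)) | set(rng.choice(range(10, 16), size=n_children + 1))
        )
        remap = {o: i for i, o in enumerate(keep)}
        ped = Pedigree(
            "1",
            [base.ids[i] for i in keep],
            np.array([remap.get(base.father[i], -1) if base.father[i] in remap
                      else -1 for i in keep]),
            np.array([remap.get(base.mother[i], -1) if base.mother[i] in remap
                      else -1 for i in keep]),
            base.sex[keep],
        )
        two_phi = 2 * ped.kinship()
        assert np.allclose(two_phi, two_phi.T)
        off = two_phi[~np.eye(ped.n, dtype=bool)]
        assert ((off >= 0) & (off <= 1)).all()
        assert ((np.diag(two_phi) >= 1) & (np.diag(two_phi) <= 2)).all()
        assert np.linalg.eigvalsh(two_phi).min() >= -1e-10


class TestReadIbd:
    def make_ibd(self, tmp_path, rows):
        p = tmp_path / "m.ibd"
        p.write_text(
            "FAMILY ID1 ID2 MARKER P0 P1 P2\n"
            + "".join(" ".join(map(str, r)) + "\n" for r in rows)
        )
        return p

    def test_sharing_from_probability_rows(self, tmp_path):
        ped = simulator.nuclear_pedigree(2)
        rows = [
            ("1", "1", "2", "m", 1, 0, 0),
            ("1", "3", "4", "m", 0.25, 0.5, 0.25),
            ("1", "1", "1", "m", 0, 0, 1),
        ]
        pis = pedio.read_ibd(self.make_ibd(tmp_path, rows), "m", {"1": ped})
        assert pis["1"][0, 1] == 0.0
        assert pis["1"][2, 3] == pytest.approx(0.5)   # 0.5/2 + 0.25
        assert pis["1"][0, 0] == 1.0

    def test_absent_pairs_default_to_twice_kinship(self, tmp_path, caplog):
        ped = simulator.nuclear_pedigree(2)
        pis = pedio.read_ibd(
            self.make_ibd(tmp_path, [("1", "3", "4", "m", 0, 0, 1)]),
            "m", {"1": ped},
        )
        assert pis["1"][2, 3] == 1.0                 # from the file
        assert pis["1"][0, 2] == pytest.approx(0.5)  # 2*phi fallback
        assert any("absent" in r.message for r in caplog.records)

    def test_bad_probability_sum_rejected(self, tmp_path):
        ped = simulator.nuclear_pedigree(1)
        with pytest.raises(PedigreeError, match="sum"):
            pedio.read_ibd(
                self.make_ibd(tmp_path, [("1", "1", "2", "m", 0.5, 0.2, 0.2)]),
                "m", {"1": ped},
            )


class TestFamilySampleAssembly:
    def test_category_mapping_ordering_and_informativeness(self, tmp_path, small_sim):
        paths = simulator.write_merlin(small_sim, tmp_path / "sim")
        pdata = pedio.read_pedigree(paths["ped"], paths["dat"])
        samples = pedio.build_family_samples(
            pdata, ("endo", "disease"), marker_x2="nullmarker", marker_x1="locus1"
        )
        assert len(samples) == small_sim.n_families
        for s in samples:
            assert (np.diff(s.y) >= 0).all()
            assert s.n_k.sum() == s.n
            assert s.informative == (len(np.unique(s.y)) > 1)

    def test_missing_phenotype_and_genotype_exclusion(self, tmp_path):
        ped_text = (
            "1 1 0 0 1 2 2 1 2\n"
            "1 2 0 0 2 1 1 1 1\n"
            "1 3 1 2 1 x 1 1 2\n"     # endo missing -> excluded
            "1 4 1 2 1 2 2 0 0\n"     # genotype missing -> excluded
        )
        dat_text = "A endo\nA disease\nM snp1\n"
        pdata = pedio.read_pedigree(*write_trio(tmp_path, ped_text, dat_text))
        (s,) = pedio.build_family_samples(pdata, ("endo", "disease"), "snp1")
        assert s.n == 2 and s.ids == ["1", "2"]
        # (Y1,Y2)=(1,1)->3, (0,0)->4
        assert s.y.tolist() == [3, 4]

    def test_ibd_matrices_align_with_retained_members(self, tmp_path, small_sim):
        paths = simulator.write_merlin(small_sim, tmp_path / "sim")
        pdata = pedio.read_pedigree(paths["ped"], paths["dat"])
        peds = pdata.pedigrees()
        ibd = {"locus2": pedio.read_ibd(paths["ibd"], "locus2", peds)}
        samples = pedio.build_family_samples(
            pdata, ("endo", "disease"), marker_x2="locus2", ibd=ibd
        )
        s0 = samples[0]
        f0 = int(s0.fam) - 1
        full_ids = small_sim.pedigree.ids
        idx = [full_ids.index(i) for i in s0.ids]
        np.testing.assert_allclose(
            s0.pi2, small_sim.pi2[f0][np.ix_(idx, idx)], atol=1e-12
        )

    def test_reference_constraints(self):
        with pytest.raises(ValueError, match="K must be at least 2"):
            FamilySample("1", ["1"], np.array([1]), 1, np.eye(1))
        with pytest.raises(ValueError, match="ordered"):
            FamilySample(
                "1", ["1", "2"], np.array([2, 1]), 2, np.eye(2)
            )
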