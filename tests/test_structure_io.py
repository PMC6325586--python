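"""Reading, splitting and writing CA trace models."""

from __future__ import annotations

import gemmi
import numpy as np
import pytest

from amyloidscreen import (
    EmptyStructureError,
    FibrilSpec,
    ResiduePoint,
    StructureParseError,
    StructureRecord,
    make_cross_beta,
    read_structure,
    split_on_breaks,
    write_structure,
)
from amyloidscreen.structure_io import ChainTrace

MULTI_MODEL_PDB = """\
HEADER    TEST
SHEET    1   A 2 VAL A   2  VAL A   4  0
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA AVAL A   2       3.800   0.000   0.000  0.60  0.00           C
ATOM      3  CA BVAL A   2       3.900   0.000   0.000  0.40  0.00           C
HETATM    4  CA  MSE A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      5  CA  GLY A   4      11.400   0.000   0.000  1.00  0.00           C
ATOM      6  CA  GLY B   1       0.000   4.800   0.000  1.00  0.00           C
ATOM      7  O   HOH C   1       0.000   9.000   0.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      8  CA  ALA A   1       9.000   9.000   9.000  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def multi_model_file(tmp_path):
    p = tmp_path / "1tst.pdb"
    p.write_text(MULTI_MODEL_PDB)
    return p


class TestReadStructure:
    def test_first_model_altloc_and_het_rules(self, multi_model_file):
        rec = read_structure(multi_model_file)
        assert rec.entry_id == "1tst"
        assert [c.chain_id for c in rec.chains] == ["A", "B"]
        a = rec.chain("A")
        # MSE is a HETATM modified residue: excluded by default
        assert [r.auth_seq_id for r in a.residues] == ["1", "2", "4"]
        assert [r.seq_index for r in a.residues] == [0, 1, 2]
        # altloc A has the higher occupancy
        assert a.residues[1].xyz[0] == pytest.approx(3.800)
        # model 2 coordinates never appear
        assert a.residues[0].xyz == (0.0, 0.0, 0.0)

    def test_extra_residues_allowlist_admits_mse(self, multi_model_file):
        rec = read_structure(multi_model_file, extra_residues=["MSE"])
        assert [r.auth_seq_id for r in rec.chain("A").residues] == ["1", "2", "3", "4"]

    def test_sheet_annotation_parsed(self, multi_model_file):
        rec = read_structure(multi_model_file)
        assert rec.sheet_annotation is not None
        (rng,) = rec.sheet_annotation
        assert (rng.chain_id, rng.start_seq, rng.end_seq) == ("A", 2, 4)

    def test_mmcif_reads_same_trace(self, multi_model_file, tmp_path):
        st = gemmi.read_structure(str(multi_model_file))
        st.setup_entities()
        cif = tmp_path / "1tst.cif"
        st.make_mmcif_document().write_file(str(cif))
        rec_pdb = read_structure(multi_model_file, format="pdb")
        rec_cif = read_structure(cif, format="mmcif")
        assert [c.chain_id for c in rec_cif.chains] == [c.chain_id for c in rec_pdb.chains]
        for cp, cc in zip(rec_pdb.chains, rec_cif.chains):
            np.testing.assert_allclose(cp.coords(), cc.coords(), atol=1e-3)

    def test_waters_only_is_empty_structure(self, tmp_path):
        p = tmp_path / "wat.pdb"
        p.write_text(
            "ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\nEND\n"
        )
        with pytest.raises(EmptyStructureError):
            read_structure(p)

    def test_unparseable_file_raises(self, tmp_path):
        p = tmp_path / "junk.cif"
        p.write_text("this is not a structure\n")
        with pytest.raises((StructureParseError, EmptyStructureError)):
            read_structure(p, format="mmcif")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "absent.pdb")


def _straight_chain(n, step=3.8, chain_id="A", gap_after=None, gap=12.0):
    pts = []
    x = 0.0
    for i in range(n):
        pts.append(ResiduePoint(chain_id, i, str(i + 1), (x, 0.0, 0.0)))
        x += gap if (gap_after is not None and i == gap_after) else step
    return ChainTrace(chain_id, tuple(pts))


class TestSplitOnBreaks:
    def test_unbroken_chain_is_single_segment(self):
        chain = _straight_chain(10)
        assert split_on_breaks(chain) == [chain]

    def test_gap_splits_into_two(self):
        chain = _straight_chain(10, gap_after=4)
        segs = split_on_breaks(chain)
        assert [len(s) for s in segs] == [5, 5]
        # parent seq_index preserved across the split
        assert segs[1].residues[0].seq_index == 5

    def test_single_residue_chain(self):
        chain = _straight_chain(1)
        assert split_on_breaks(chain) == [chain]

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        pts = tuple(
            ResiduePoint("A", i, str(i + 1), tuple(rng.uniform(-30, 30, 3)))
            for i in range(n)
        )
        chain = ChainTrace("A", pts)
        segs = split_on_breaks(chain, max_gap=4.5)
        assert sum(len(s) for s in segs) == n
        flat = tuple(r for s in segs for r in s.residues)
        assert flat == pts


class TestWriteStructure:
    @pytest.mark.parametrize("n_chains,n_residues", [(2, 14), (5, 8), (1, 3)])
    def test_round_trip(self, tmp_path, n_chains, n_residues):
        rec = make_cross_beta(
            FibrilSpec(n_chains=n_chains, n_residues=n_residues, noise_sd=0.3, seed=7)
        )
        path = tmp_path / f"{rec.entry_id}.pdb"
        write_structure(rec, path)
        back = read_structure(path)
        assert back.entry_id == rec.entry_id
        assert [c.chain_id for c in back.chains] == [c.chain_id for c in rec.chains]
        for c0, c1 in zip(rec.chains, back.chains):
            assert [r.auth_seq_id for r in c0.residues] == [
                r.auth_seq_id for r in c1.residues
            ]
            np.testing.assert_allclose(c0.coords(), c1.coords(), atol=1e-3)

    def test_fixed_width_rounding(self, tmp_path):
        rec = StructureRecord(
            "big",
            [
                ChainTrace(
                    "A",
                    (
                        ResiduePoint("A", 0, "1", (1234.5678, 0.0, 0.0)),
                        ResiduePoint("A", 1, "2", (1238.3678, 0.0, 0.0)),
                        ResiduePoint("A", 2, "3", (1242.1678, 0.0, 0.0)),
                    ),
                )
            ],
        )
        path = tmp_path / "big.pdb"
        write_structure(rec, path)
        assert "1234.568" in path.read_text()
        back = read_structure(path)
        assert back.chain("A").residues[0].xyz[0] == pytest.approx(1234.5678, abs=1e-3)

    def test_empty_record_rejected(self, tmp_path):
        rec = StructureRecord("x", [])
        with pytest.raises(ValueError):
            write_structure(rec, tmp_path / "x.pdb")

    def test_chain_alphabet_exhaustion(self, tmp_path):
        chains = [
            ChainTrace(cid, (ResiduePoint(cid, 0, "1", (float(i), 0.0, 0.0)),))
            for i, cid in enumerate(f"c{i}" for i in range(63))
        ]
        # 63 chains cannot be written: ids exceed the one-character alphabet
        rec = StructureRecord("many", chains)
        with pytest.raises(ValueError):
            write_structure(rec, tmp_path / "many.pdb")
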