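"""Feature encoding: one-hot basics, shift normalization/binarization,
dataset assembly."""

import numpy as np
import pandas as pd
import pytest

from glycoplan.features import (
    SHIFT_SLOTS,
    DataError,
    FeatureConfig,
    SchemaError,
    ShiftEncoder,
    assemble_dataset,
    encode_basic,
    encode_shifts,
)
from glycoplan.fixtures import GeneratorConfig, generate_rrv_dataset


def props(sugar="Gal", anomeric="b", pg2="OBz", pg3="OBn", pg4="OBn", pg6="OBn"):
    return {"sugar_type": sugar, "anomeric": anomeric,
            "pg_2": pg2, "pg_3": pg3, "pg_4": pg4, "pg_6": pg6}


class TestEncodeBasic:
    def test_hex_class_binarized(self):
        v = encode_basic(props("Gal"))
        assert v["sugar_class_Hex"] == 1.0
        assert v["sugar_class_HexNAc"] == 0.0

    def test_sugar_type_one_hot_sums_to_one(self):
        v = encode_basic(props("Gal"))
        block = [v[f"sugar_type_{s}"] for s in ("Gal", "Glc", "Man", "GalNAc", "GlcNAc")]
        assert sum(block) == 1.0 and v["sugar_type_Gal"] == 1.0

    def test_pg_indicator_exclusive(self):
        v = encode_basic(props(pg2="OLev"))
        pg2 = {k: x for k, x in v.items() if k.startswith("pg2_")}
        assert pg2["pg2_OLev"] == 1.0
        assert sum(pg2.values()) == 1.0

    def test_hexnac_amine_token_allowed_at_position_2(self):
        v = encode_basic(props("GlcNAc", pg2="NHTroc"))
        assert v["pg2_NHTroc"] == 1.0

    def test_unknown_token_raises_schema_error_listing_allowed(self):
        with pytest.raises(SchemaError) as e:
            encode_basic(props(pg3="OXyz"))
        assert "OXyz" in str(e.value) and "OBn" in str(e.value)

    def test_ordinal_codes_in_unit_interval(self):
        v = encode_basic(props(), binarize=False, ordinal=True)
        assert set(v) == {"sugar_type_ord", "sugar_class_ord", "anomeric_ord",
                          "pg2_ord", "pg3_ord", "pg4_ord", "pg6_ord"}
        assert all(0.0 <= x <= 1.0 for x in v.values())


def shift_frame(rows):
    return pd.DataFrame(rows, columns=list(SHIFT_SLOTS), dtype=float)


class TestShiftEncoding:
    def setup_method(self):
        rng = np.random.default_rng(7)
        vals = np.hstack([
            rng.uniform(3.0, 6.0, size=(8, 7)),      # proton slots
            rng.uniform(60.0, 100.0, size=(8, 6)),   # carbon slots
        ])
        self.table = shift_frame(vals.tolist())

    def test_training_min_maps_to_zero_and_max_to_one(self):
        enc = ShiftEncoder().fit(self.table)
        out = enc.transform(self.table, "normalized")
        for s in SHIFT_SLOTS:
            col = out[f"cs_{s}_norm"]
            assert col.min() == pytest.approx(0.0)
            assert col.max() == pytest.approx(1.0)

    def test_constant_slot_normalizes_to_zero_single_bin(self):
        t = self.table.copy()
        t["H1"] = 5.0
        out = encode_shifts(t, "both")
        assert (out["cs_H1_norm"] == 0.0).all()
        assert (out["cs_H1_bin0"] == 1.0).all()
        assert not any(c.startswith("cs_H1_bin1") for c in out.columns)

    def test_binarized_one_bin_active_per_slot(self):
        out = encode_shifts(self.table, "binarized")
        for s in SHIFT_SLOTS:
            bins = [c for c in out.columns if c.startswith(f"cs_{s}_bin")]
            assert (out[bins].sum(axis=1) == 1.0).all()

    def test_out_of_range_values_clip_into_unit_interval(self):
        enc = ShiftEncoder().fit(self.table)
        new = self.table.copy()
        new.iloc[0, 0] = 99.0
        out = enc.transform(new, "normalized")
        assert out.iloc[0, 0] == pytest.approx(1.0)
        assert enc.clip_events >= 1

    def test_missing_h62_imputed_and_flagged(self):
        t = self.table.copy()
        t.loc[0, "H6-2"] = np.nan
        enc = ShiftEncoder().fit(t)
        out = enc.transform(t, "normalized")
        assert "cs_H6-2_missing" in out.columns
        assert out["cs_H6-2_missing"].iloc[0] == 1.0
        assert np.isfinite(out["cs_H6-2_norm"]).all()

    def test_infinite_shift_is_data_error(self):
        t = self.table.copy()
        t.loc[0, "C1"] = np.inf
        with pytest.raises(DataError):
            ShiftEncoder().fit(t)


class TestAssembleDataset:
    def test_bp_plus_normalized_cs_length_arithmetic(self):
        data = generate_rrv_dataset(
            GeneratorConfig(n_bbls=20, seed=3),
            feature_config=FeatureConfig(blocks=("BP", "CS"), cs_mode="normalized"),
        )
        ds = data.dataset
        n_bp = len(ds.feature_blocks["BP"])
        # 5 sugar types + 2 classes + 2 anomeric + (11+3) pg2 + 3*11 pg tokens
        assert n_bp == 5 + 2 + 2 + 14 + 33
        assert len(ds.feature_blocks["CS"]) == 13
        assert len(ds.feature_names) == n_bp + 13

    def test_ln_transform_round_trips(self):
        data = generate_rrv_dataset(GeneratorConfig(n_bbls=15, seed=4))
        ds = data.dataset
        assert np.allclose(np.exp(ds.ln_rrv), ds.rrv)

    def test_unit_rrv_maps_to_zero_log(self):
        import pandas as pd

        from glycoplan.features import Dataset

        ds = Dataset(
            X=pd.DataFrame({"f": [0.1, 0.2]}, index=["a", "b"]),
            rrv=pd.Series([1.0, 10.0], index=["a", "b"]),
            ln_rrv=pd.Series(np.log([1.0, 10.0]), index=["a", "b"]),
        )
        assert ds.ln_rrv["a"] == 0.0

    def test_default_size_mirrors_training_library(self):
        data = generate_rrv_dataset(GeneratorConfig(seed=0))
        assert data.dataset.n == 117
        sugars = {b.residues.root.sugar_type for b in data.library}
        assert "Neu5Ac" not in sugars

    def test_sialic_acid_rows_excluded(self):
        from glycoplan.glycan import BuildingBlock, GlycanTree, Residue

        data = generate_rrv_dataset(GeneratorConfig(n_bbls=10, seed=5))
        sa = BuildingBlock(
            index="SA0", name="SA0", rrv=2.0,
            residues=GlycanTree([
                Residue(id=1, sugar_type="Neu5Ac", anomeric_form="a",
                        substituents={4: "OAc", 7: "OAc", 8: "OAc", 9: "OAc"})
            ]),
        )
        shift = data.shift_table.copy()
        desc = data.descriptor_table.copy()
        ds = assemble_dataset(list(data.library) + [sa], shift, desc,
                              FeatureConfig(cs_mode="normalized"))
        assert "SA0" not in ds.X.index
        assert ds.n == 10

    def test_missing_table_key_is_join_error_listing_indices(self):
        data = generate_rrv_dataset(GeneratorConfig(n_bbls=8, seed=6))
        shift = data.shift_table.drop(index="S003")
        with pytest.raises(DataError) as e:
            assemble_dataset(data.library, shift, data.descriptor_table,
                             FeatureConfig(cs_mode="normalized"))
        assert "S003" in str(e.value)

    def test_nonpositive_rrv_is_target_error(self):
        data = generate_rrv_dataset(GeneratorConfig(n_bbls=6, seed=7))
        data.library[0].rrv = 0.0
        with pytest.raises(DataError):
            assemble_dataset(data.library, data.shift_table,
                             data.descriptor_table,
                             FeatureConfig(cs_mode="normalized"))

    def test_rescaling_idempotent_on_training_data(self):
        data = generate_rrv_dataset(GeneratorConfig(n_bbls=25, seed=8))
        from sklearn.preprocessing import MinMaxScaler

        X = data.dataset.X.to_numpy()
        z = MinMaxScaler(clip=True).fit(X).transform(X)
        assert z.min() >= 0.0 and z.max() <= 1.0
        # rescaling already-rescaled data changes nothing (idempotence)
        z2 = MinMaxScaler(clip=True).fit(z).transform(z)
        assert np.allclose(z, z2)
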