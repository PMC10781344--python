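"""VIA parsing, rasterization (vs point-in-polygon oracles), statistics."""

import json

import numpy as np
import pytest
import shapely

from midseg.dataio import (AnnotationSet, Region, ViaParseError, dataset_stats,
                           default_label_map, load_mask_png, parse_via,
                           rasterize, save_mask_png, size_category, write_via,
                           load_label_map, save_label_map)


def _via_doc(regions, filename="img0.png", w=64, h=64):
    return {
        filename: {
            "filename": filename,
            "size": -1,
            "regions": regions,
            "file_attributes": {"width": w, "height": h},
        }
    }


def _poly_region(xs, ys, label):
    return {
        "shape_attributes": {"name": "polygon", "all_points_x": xs, "all_points_y": ys},
        "region_attributes": {"class": label},
    }


def _shapely_fill(poly, h, w):
    """Independent oracle: pixel-center point-in-polygon via shapely."""
    ring = shapely.Polygon(poly)
    ys, xs = np.mgrid[0:h, 0:w]
    pts_x = (xs + 0.5).ravel()
    pts_y = (ys + 0.5).ravel()
    inside = shapely.contains_xy(ring, pts_x, pts_y)
    return inside.reshape(h, w)


# ---------------------------------------------------------------------------
# parsing


def test_parse_rectangle_white_rice():
    doc = _via_doc([_poly_region([10, 20, 20, 10], [10, 10, 20, 20], "White rice")])
    sets, warnings = parse_via(doc, default_label_map())
    assert len(sets) == 1 and len(sets[0].regions) == 1
    region = sets[0].regions[0]
    assert region.class_id == 1 and len(region.polygon) == 4
    assert warnings["unknown_class"] == 0


def test_parse_zero_regions():
    sets, _ = parse_via(_via_doc([]), default_label_map())
    assert sets[0].regions == []


def test_parse_skips_non_polygon_with_warning():
    doc = _via_doc([
        {"shape_attributes": {"name": "rect", "x": 1, "y": 1, "width": 5, "height": 5},
         "region_attributes": {"class": "Beans"}},
        _poly_region([1, 6, 6], [1, 1, 6], "Beans"),
    ])
    sets, warnings = parse_via(doc, default_label_map())
    assert warnings["non_polygon"] == 1
    assert len(sets[0].regions) == 1


def test_parse_unknown_label_reported():
    doc = _via_doc([_poly_region([1, 6, 6], [1, 1, 6], "Pizza")])
    sets, warnings = parse_via(doc, default_label_map())
    assert warnings["unknown_class"] == 1 and "Pizza" in warnings["skipped_labels"]
    with pytest.raises(ViaParseError, match="Pizza"):
        parse_via(doc, default_label_map(), strict=True)


def test_parse_malformed_json_names_location():
    with pytest.raises(ViaParseError, match="line"):
        parse_via('{"broken": ', default_label_map())


def test_via_roundtrip(rng):
    lm = default_label_map()
    sets = []
    for i in range(3):
        ann = AnnotationSet(f"im{i}.png", 48, 40)
        for _ in range(rng.integers(1, 4)):
            n = int(rng.integers(3, 8))
            poly = np.column_stack([rng.uniform(0, 48, n), rng.uniform(0, 40, n)])
            cid = int(rng.integers(1, 11))
            name = [k for k, v in lm.items() if v == cid][0]
            ann.regions.append(Region(poly, cid, name))
        sets.append(ann)
    doc = write_via(sets)
    back, _ = parse_via(json.loads(json.dumps(doc)), lm)
    assert len(back) == len(sets)
    for a, b in zip(sets, back):
        assert a.image_id == b.image_id and (a.width, a.height) == (b.width, b.height)
        assert len(a.regions) == len(b.regions)
        for ra, rb in zip(a.regions, b.regions):
            assert ra.class_id == rb.class_id
            np.testing.assert_allclose(ra.polygon, rb.polygon)


# ---------------------------------------------------------------------------
# rasterization


def test_rasterize_empty_is_all_background():
    ann = AnnotationSet("x", 32, 24)
    assert (rasterize(ann, 11) == 0).all()


def test_square_fill_pixel_centers():
    """A [10,20]x[10,20] square covers exactly the 100 pixel centers
    10.5..19.5 under center sampling."""
    ann = AnnotationSet("x", 512, 512)
    ann.regions.append(Region(np.array([[10, 10], [20, 10], [20, 20], [10, 20]]), 1, "White rice"))
    mask = rasterize(ann, 11)
    assert int((mask == 1).sum()) == 100
    assert mask[10, 10] == 1 and mask[19, 19] == 1 and mask[20, 20] == 0


def test_polygon_fill_matches_shapely_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(3, 9))
        poly = np.column_stack([rng.uniform(0, 48, n), rng.uniform(0, 48, n)])
        ann = AnnotationSet("x", 48, 48)
        ann.regions.append(Region(poly, 1, "c"))
        mask = rasterize(ann, 2)
        # shapely's simple-polygon fill equals ours only for non-self-
        # intersecting rings; use the convex hull to guarantee that
        hull = shapely.convex_hull(shapely.MultiPoint(poly))
        hull_poly = np.asarray(hull.exterior.coords)[:-1]
        ann2 = AnnotationSet("x", 48, 48)
        ann2.regions.append(Region(hull_poly, 1, "c"))
        mask2 = rasterize(ann2, 2)
        np.testing.assert_array_equal(mask2 == 1, _shapely_fill(hull_poly, 48, 48))


def test_overlap_painted_in_annotation_order():
    ann = AnnotationSet("x", 32, 32)
    ann.regions.append(Region(np.array([[2, 2], [20, 2], [20, 20], [2, 20]]), 1, "a"))
    ann.regions.append(Region(np.array([[10, 10], [28, 10], [28, 28], [10, 28]]), 2, "b"))
    mask = rasterize(ann, 3)
    assert mask[15, 15] == 2  # overlap belongs to the later region
    assert mask[5, 5] == 1
    assert mask[25, 25] == 2


def test_degenerate_region_surfaced_not_dropped():
    ann = AnnotationSet("x", 32, 32)
    ann.regions.append(Region(np.array([[5.1, 5.1], [5.2, 5.1], [5.15, 5.2]]), 1, "tiny"))
    mask, degenerate = rasterize(ann, 2, report_degenerate=True)
    assert degenerate == 1 and (mask == 0).all()


def test_rasterize_class_overflow_rejected():
    ann = AnnotationSet("x", 16, 16)
    ann.regions.append(Region(np.array([[1, 1], [9, 1], [9, 9]]), 12, "c"))
    with pytest.raises(ValueError, match="class id 12"):
        rasterize(ann, 11)


# ---------------------------------------------------------------------------
# size bands


@pytest.mark.parametrize(
    "obj,img,expect",
    [
        (262144, 262144, "large"),          # full image, r = 1
        (10000, 262144, "small"),           # 100x100 in 512x512: r = 0.0381
        (13108, 262144, "medium"),          # r = 0.050003 (>= 5%)
        (52429, 262144, "large"),           # r just above 20%
        (52428, 262144, "medium"),          # r just below/at 20%
    ],
)
def test_size_category_thresholds(obj, img, expect):
    assert size_category(obj, img) == expect


def test_size_category_errors():
    with pytest.raises(ValueError):
        size_category(10, 0)
    with pytest.raises(ValueError):
        size_category(11, 10)


# ---------------------------------------------------------------------------
# statistics


def test_dataset_stats_against_generator_bookkeeping(small_synth):
    stats = dataset_stats(small_synth.annotations,
                          num_classes=small_synth.config.n_classes + 1)
    # occurrences match the generator's records exactly
    want_occ = {}
    want_bands = {"small": 0, "medium": 0, "large": 0}
    for recs in small_synth.truth:
        for r in recs:
            want_occ[r["class_id"]] = want_occ.get(r["class_id"], 0) + 1
            want_bands[r["band"]] += 1
    assert stats.occurrences == dict(sorted(want_occ.items()))
    assert stats.size_category_counts == want_bands
    # classes-per-image from the records
    want_cpi = {}
    for recs in small_synth.truth:
        n = len({r["class_id"] for r in recs})
        want_cpi[n] = want_cpi.get(n, 0) + 1
    assert stats.classes_per_image_counts == dict(sorted(want_cpi.items()))
    assert sum(stats.classes_per_image.values()) == pytest.approx(1.0, abs=1e-9)
    assert sum(stats.size_categories.values()) == pytest.approx(1.0, abs=1e-9)


def test_stats_single_object():
    ann = AnnotationSet("x", 64, 64)
    ann.regions.append(Region(np.array([[4, 4], [30, 4], [30, 30], [4, 30]]), 3, "Koki"))
    stats = dataset_stats([ann], num_classes=11)
    assert stats.occurrences == {3: 1}
    assert stats.classes_per_image == {1: 1.0}
    table = stats.table()
    assert "One Class" in table and "Four Classes" in table
    assert table.splitlines()[1].startswith("100.00%")


def test_stats_bbox_mode_differs_from_mask_mode():
    ann = AnnotationSet("x", 64, 64)
    # a thin triangle: bbox area far exceeds mask area
    ann.regions.append(Region(np.array([[2, 2], [62, 2], [2, 8]]), 1, "c"))
    st_mask = dataset_stats([ann], num_classes=2, mode="mask")
    st_bbox = dataset_stats([ann], num_classes=2, mode="bbox")
    assert st_mask.size_category_counts != st_bbox.size_category_counts


# ---------------------------------------------------------------------------
# PNG / label-map round trips


def test_mask_png_roundtrip(tmp_path, rng):
    mask = rng.integers(0, 11, size=(37, 23))
    path = tmp_path / "m.png"
    save_mask_png(mask, path)
    np.testing.assert_array_equal(load_mask_png(path), mask)


def test_label_map_roundtrip(tmp_path):
    lm = default_label_map()
    path = tmp_path / "labels.yaml"
    save_label_map(lm, path)
    assert load_label_map(path) == lm
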