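"""Island detection and genomic-context classification against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from methylseas.annotation import (
    CpGIsland,
    FunctionalClass,
    GenomicInterval,
    RegionClass,
    annotate_probes,
    assign_functional_regions,
    classify_gene_context,
    classify_neighborhood,
    detect_cpg_islands,
)

WINDOW = 200


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def window_qualifies(seq: str, min_gc=0.5, min_oe=0.6) -> bool:
    """Naive single-window check used as the independent oracle."""
    if any(b not in "ACGT" for b in seq):
        return False
    n_c, n_g = seq.count("C"), seq.count("G")
    n_cg = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
    gc = (n_c + n_g) / len(seq)
    oe = n_cg * len(seq) / (n_c * n_g) if n_c and n_g else 0.0
    return gc > min_gc and oe >= min_oe - 1e-12


def brute_force_islands(seq: str, window=WINDOW) -> list[tuple[int, int]]:
    """Enumerate every qualifying window, then union intervals."""
    spans = [(i, i + window) for i in range(len(seq) - window + 1)
             if window_qualifies(seq[i : i + window])]
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def brute_force_neighborhood(island_spans, pos):
    best = None  # (distance, start, north)
    for s, e in island_spans:
        if s <= pos < e:
            return RegionClass.ISLAND
        if pos >= e:
            cand = (pos - e, s, False)
        else:
            cand = (s - pos - 1, s, True)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return RegionClass.OPEN_SEA
    d, _, north = best
    if d <= 2000:
        return RegionClass.N_SHORE if north else RegionClass.S_SHORE
    if d <= 4000:
        return RegionClass.N_SHELF if north else RegionClass.S_SHELF
    return RegionClass.OPEN_SEA


# ---------------------------------------------------------------------------
# island detection
# ---------------------------------------------------------------------------

def test_homopolymer_has_no_islands():
    assert detect_cpg_islands("A" * 1000) == []


def test_sequence_shorter_than_window_is_empty():
    assert detect_cpg_islands("ACGT" * 10) == []


def test_gc_threshold_is_strict():
    # "CGTA"*50: GC exactly 50%, obs/exp far above 0.6 -> must not qualify
    seq = "CGTA" * 50
    assert window_qualifies(seq) is False
    assert detect_cpg_islands(seq) == []


def test_obs_exp_threshold_is_inclusive():
    # 60 C, 50 G, 90 A; exactly 9 CpG -> obs/exp = 9*200/3000 = 0.6 exactly,
    # GC = 55% -> qualifies at the inclusive boundary
    seq = "CG" * 9 + "CA" * 50 + "C" + "AG" * 40 + "G"
    assert len(seq) == 200
    assert seq.count("C") == 60 and seq.count("G") == 50
    islands = detect_cpg_islands(seq)
    assert len(islands) == 1
    assert islands[0].obs_exp_ratio == pytest.approx(0.6)
    # one CpG fewer -> obs/exp 0.544 < 0.6 -> no island
    weakened = seq.replace("CG", "CA", 1)
    assert detect_cpg_islands(weakened) == []


def test_windows_containing_n_never_qualify():
    seq = "ACGCGG" * 40  # qualifying everywhere
    broken = seq[:100] + "N" + seq[101:]
    islands = detect_cpg_islands(broken)
    # windows spanning the N are disqualified, so no island covers position 100
    for isl in islands:
        assert not isl.interval.contains(100)


@pytest.mark.parametrize("seed", range(10))
def test_detection_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=2000, p=[0.2, 0.3, 0.3, 0.2]))
    expected = brute_force_islands(seq)
    got = [(i.interval.start, i.interval.end) for i in detect_cpg_islands(seq)]
    assert got == expected


def test_detection_invariant_to_chunked_scanning():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), size=3000, p=[0.2, 0.3, 0.3, 0.2]))
    # evaluate every window inside overlapping chunks, then union: must equal
    # the single-pass result
    spans = []
    for lo in (0, 1000, 2000):
        chunk = seq[lo : lo + 1000 + WINDOW - 1]
        for i in range(len(chunk) - WINDOW + 1):
            if window_qualifies(chunk[i : i + WINDOW]):
                spans.append((lo + i, lo + i + WINDOW))
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    got = [(i.interval.start, i.interval.end) for i in detect_cpg_islands(seq)]
    assert got == [tuple(iv) for iv in merged]


def test_planted_islands_recovered(genome):
    seq, planted, _ = genome
    detected = detect_cpg_islands(seq)
    assert len(detected) == len(planted)
    for det, truth in zip(detected, planted):
        assert det.interval.start < truth.end and truth.start < det.interval.end
        assert det.gc_fraction > 0.5 and det.obs_exp_ratio >= 0.6


# ---------------------------------------------------------------------------
# neighborhood classification
# ---------------------------------------------------------------------------

def _islands(*spans):
    return [CpGIsland(GenomicInterval("chr1", s, e), 0.6, 1.0) for s, e in spans]


def test_position_inside_island():
    assert classify_neighborhood(_islands((1000, 1400)), "chr1", 1200) is RegionClass.ISLAND


@pytest.mark.parametrize("pos,expected", [
    (12499, RegionClass.S_SHORE),
    (12500, RegionClass.S_SHORE),   # d = 2000, inclusive
    (12501, RegionClass.S_SHELF),
    (14500, RegionClass.S_SHELF),   # d = 4000, inclusive
    (14501, RegionClass.OPEN_SEA),  # d = 4001
    (9000, RegionClass.N_SHORE),
    (6500, RegionClass.N_SHELF),
    (100, RegionClass.OPEN_SEA),
])
def test_shore_shelf_open_sea_boundaries(pos, expected):
    assert classify_neighborhood(_islands((10000, 10500)), "chr1", pos) is expected


def test_no_islands_means_open_sea():
    assert classify_neighborhood([], "chr1", 5) is RegionClass.OPEN_SEA


def test_overlapping_islands_rejected():
    with pytest.raises(ValueError):
        classify_neighborhood(_islands((100, 300), (200, 500)), "chr1", 50)


def test_neighborhood_matches_brute_force():
    rng = np.random.default_rng(42)
    spans = [(10000, 10400), (20000, 21000), (40000, 40250)]
    islands = _islands(*spans)
    for pos in rng.integers(0, 50000, size=1000):
        pos = int(pos)
        assert classify_neighborhood(islands, "chr1", pos) is \
            brute_force_neighborhood(spans, pos), pos


def test_reflection_symmetry_swaps_north_south():
    spans = [(10000, 10400), (20000, 21000)]
    islands = _islands(*spans)
    k = 50000
    mirrored = _islands(*sorted((k - e, k - s) for s, e in spans))
    swap = {RegionClass.N_SHORE: RegionClass.S_SHORE,
            RegionClass.S_SHORE: RegionClass.N_SHORE,
            RegionClass.N_SHELF: RegionClass.S_SHELF,
            RegionClass.S_SHELF: RegionClass.N_SHELF}
    rng = np.random.default_rng(7)
    for pos in rng.integers(0, k, size=500):
        pos = int(pos)
        cls = classify_neighborhood(islands, "chr1", pos)
        mirrored_cls = classify_neighborhood(mirrored, "chr1", k - 1 - pos)
        assert mirrored_cls is swap.get(cls, cls)


# ---------------------------------------------------------------------------
# functional regions and gene context
# ---------------------------------------------------------------------------

def _gene(gene_id, start, end, strand, biotype="coding", exons=None, utr5="", utr3=""):
    tss = start if strand == "+" else end
    return dict(gene_id=gene_id, chrom="chr1", start=start, end=end, strand=strand,
                biotype=biotype, tss=tss,
                exons=exons or f"{start}-{end}", utr5=utr5, utr3=utr3)


def test_tss200_upstream_plus_strand():
    gm = pd.DataFrame([_gene("gA", 5000, 8000, "+")])
    assert assign_functional_regions(gm, "chr1", 4801) == {(FunctionalClass.TSS200, "gA")}
    assert assign_functional_regions(gm, "chr1", 4800) == {(FunctionalClass.TSS200, "gA")}   # u = 200 inclusive
    assert assign_functional_regions(gm, "chr1", 4799) == {(FunctionalClass.TSS1500, "gA")}  # u = 201
    assert assign_functional_regions(gm, "chr1", 3500) == {(FunctionalClass.TSS1500, "gA")}  # u = 1500 inclusive
    assert assign_functional_regions(gm, "chr1", 3499) == set()


def test_tss200_upstream_minus_strand():
    gm = pd.DataFrame([_gene("gB", 2000, 5000, "-")])
    assert assign_functional_regions(gm, "chr1", 5200) == {(FunctionalClass.TSS200, "gB")}
    assert assign_functional_regions(gm, "chr1", 5201) == {(FunctionalClass.TSS1500, "gB")}


def test_feature_precedence_within_gene():
    gm = pd.DataFrame([_gene(
        "gC", 1000, 4000, "+",
        exons="1000-1500;2000-2500;3500-4000",
        utr5="1000-1100", utr3="3900-4000")])
    cases = {
        1050: FunctionalClass.UTR5,
        1200: FunctionalClass.FIRST_EXON,
        2200: FunctionalClass.BODY,   # second exon is plain body
        3950: FunctionalClass.UTR3,
        1700: FunctionalClass.BODY,   # intron
    }
    for pos, cls in cases.items():
        assert assign_functional_regions(gm, "chr1", pos) == {(cls, "gC")}, pos


def test_overlapping_genes_match_brute_force():
    genes = [
        _gene("g1", 1000, 4000, "+", exons="1000-1500;3000-4000", utr5="1000-1100"),
        _gene("g2", 2000, 6000, "-", biotype="miR", exons="2000-2500;5500-6000",
              utr5="5900-6000", utr3="2000-2100"),
        _gene("g3", 3500, 5000, "+", biotype="noncoding"),
        _gene("g4", 7000, 9000, "+", utr3="8900-9000"),
    ]
    gm = pd.DataFrame(genes)
    rng = np.random.default_rng(5)

    def oracle(pos):
        out = set()
        for g in genes:
            u = (g["tss"] - pos) if g["strand"] == "+" else (pos - g["tss"])
            if 1 <= u <= 200:
                out.add((FunctionalClass.TSS200, g["gene_id"])); continue
            if 200 < u <= 1500:
                out.add((FunctionalClass.TSS1500, g["gene_id"])); continue
            if not (g["start"] <= pos < g["end"]):
                continue
            def inside(spec):
                return any(int(t.split("-")[0]) <= pos < int(t.split("-")[1])
                           for t in spec.split(";") if t)
            exon_list = [tuple(map(int, t.split("-"))) for t in g["exons"].split(";")]
            first = exon_list[0] if g["strand"] == "+" else exon_list[-1]
            if g["utr5"] and inside(g["utr5"]):
                cls = FunctionalClass.UTR5
            elif first[0] <= pos < first[1]:
                cls = FunctionalClass.FIRST_EXON
            elif g["utr3"] and inside(g["utr3"]):
                cls = FunctionalClass.UTR3
            else:
                cls = FunctionalClass.BODY
            out.add((cls, g["gene_id"]))
        return out

    for pos in rng.integers(0, 10000, size=50):
        pos = int(pos)
        assert assign_functional_regions(gm, "chr1", pos) == oracle(pos), pos


def test_gene_with_invalid_span_rejected():
    gm = pd.DataFrame([_gene("bad", 5000, 5000, "+")])
    gm.loc[0, "end"] = 4000
    with pytest.raises(ValueError):
        assign_functional_regions(gm, "chr1", 4500)


def test_gene_context_precedence():
    gm = pd.DataFrame([
        _gene("c1", 0, 10, "+", biotype="coding"),
        _gene("m1", 0, 10, "+", biotype="miR"),
        _gene("n1", 0, 10, "+", biotype="noncoding"),
    ])
    body = FunctionalClass.BODY
    assert classify_gene_context(set(), gm).value == "intergenic"
    assert classify_gene_context({(body, "c1"), (body, "m1")}, gm).value == "coding"
    assert classify_gene_context({(body, "m1")}, gm).value == "noncoding"
    assert classify_gene_context({(body, "n1"), (body, "m1")}, gm).value == "noncoding"
    bad = pd.DataFrame([_gene("x", 0, 10, "+", biotype="mystery")])
    with pytest.raises(ValueError):
        classify_gene_context({(body, "x")}, bad)


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

def test_empty_manifest_annotates_empty():
    man = pd.DataFrame(columns=["probe_id", "chrom", "pos"])
    gm = pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand",
                               "biotype", "tss", "exons", "utr5", "utr3"])
    ann, rejects = annotate_probes(man, {"chr1": []}, gm)
    assert ann.empty and rejects.empty


def test_unknown_chromosome_goes_to_rejects():
    man = pd.DataFrame({"probe_id": ["p1", "p2"], "chrom": ["chr1", "chr9"],
                        "pos": [100, 100]})
    gm = pd.DataFrame([_gene("g", 5000, 6000, "+")])
    ann, rejects = annotate_probes(man, {"chr1": []}, gm)
    assert list(ann["probe_id"]) == ["p1"]
    assert list(rejects["probe_id"]) == ["p2"]


def test_probes_in_planted_islands_annotated_island(genome, manifest):
    seq, islands, gene_models = genome
    detected = {"chr1": detect_cpg_islands(seq, "chr1")}
    ann, rejects = annotate_probes(manifest, detected, gene_models)
    assert len(ann) == len(manifest) and rejects.empty
    hint = manifest.set_index("probe_id")["region_hint"]
    regions = ann.set_index("probe_id")["region"]
    island_probes = hint[hint == "island"].index
    assert (regions.loc[island_probes] == "Island").all()
    sea_probes = hint[hint == "open_sea"].index
    assert (regions.loc[sea_probes] == "OpenSea").all()
    # open-sea probe outside all genes: no assignment, intergenic
    outside = ann[(ann["region"] == "OpenSea") & (ann["functional"] == "")]
    assert (outside["gene_context"] == "intergenic").all()
    # miR flags exist (open-sea miR gene bodies are probed)
    assert ann["is_mir"].any()
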