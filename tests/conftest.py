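import numpy as np
import pytest

import polreloc as pr
from polreloc import polii
from polreloc.coverage import Peak


@pytest.fixture(scope="session")
def sim():
    """One default simulated dataset shared across tests (seed 1)."""
    return pr.simulate_dataset(pr.SimConfig(seed=1))


@pytest.fixture(scope="session")
def toy_annotation():
    """A small hand-built annotation for geometric tests.

    chrA (50 kb): GENE1 (+, 10000-12000), GENE2 (-, 20000-22000),
    TRNA1 (30000-30080), SNR1 snRNA (40000-40500).
    """
    chroms = {"chrA": 50_000, "chrB": 20_000}
    genes = [
        pr.GeneModel("GENE1", pr.Interval("chrA", 10_000, 12_000), "+",
                     "mRNA", pr.Interval("chrA", 10_000, 12_000)),
        pr.GeneModel("GENE2", pr.Interval("chrA", 20_000, 22_000), "-",
                     "mRNA", pr.Interval("chrA", 20_000, 22_000)),
        pr.GeneModel("TRNA1", pr.Interval("chrA", 30_000, 30_080), "+", "tRNA"),
        pr.GeneModel("SNR1", pr.Interval("chrA", 40_000, 40_500), "+", "snRNA"),
    ]
    return pr.GenomeAnnotation(chrom_lengths=chroms, genes=genes)


def merge_flagged_bins(intervals, condition="", polii_label="independent"):
    """Merge adjacent flagged bins into peaks (helper for end-to-end tests)."""
    peaks = []
    for iv in intervals:
        if (
            peaks
            and peaks[-1].interval.chrom == iv.chrom
            and peaks[-1].interval.end == iv.start
        ):
            peaks[-1].interval = pr.Interval(
                iv.chrom, peaks[-1].interval.start, iv.end
            )
        else:
            peaks.append(Peak(interval=iv, condition=condition, polii=polii_label))
    return peaks


def independent_peaks_from_sim(sim_result, condition="minusN"):
    """Run the fit + flag + merge path on a simulated condition."""
    table = polii.BinTable(
        sim_result.bins,
        sim_result.track("Rpb3", condition).values,
        sim_result.track("Hda1", condition).values,
    )
    polii.robust_exp_fit(table)
    polii.flag_outlier_bins(table)
    return table, merge_flagged_bins(
        polii.independent_bin_intervals(table), condition
    )
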