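"""Exact HU histograms of segmented volumes and attenuation-fraction biomarkers.

The histogram is an exact integer-HU frequency map over the segmented voxels
(no binning, smoothing or density normalisation).  On top of it the report
computes the descriptors used to characterise lung phenotypes: the modal
100-HU bin (healthy lungs peak in [−900, −800)), the fraction of voxels below
−950 HU (emphysematous destruction) and the fraction above −200 HU
(ground-glass, reticulation, fibrosis).  "Below" and "above" are strict.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

from lungembed.errors import FormatError
from lungembed.volume import LabeledVolume


@dataclass
class HUHistogram:
    """Exact map from integer HU value to voxel count."""

    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = {int(k): int(v) for k, v in self.counts.items()}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, HUHistogram):
            return NotImplemented
        return self.counts == other.counts


@dataclass
class HistogramReport:
    """Summary descriptors of a segmented-lung HU histogram.

    ``modal_bin`` is the left edge pair ``(b, b + bin_width)`` of the
    left-closed right-open bin with the largest summed count (ties resolved
    toward the lowest-HU bin); it is None for an empty histogram.
    """

    total: int
    modal_bin: tuple[int, int] | None
    frac_below_low: float
    frac_above_high: float
    t_low: int = -950
    t_high: int = -200
    bin_width: int = 100

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "modal_bin": list(self.modal_bin) if self.modal_bin else None,
            f"frac_below_{self.t_low}": self.frac_below_low,
            f"frac_above_{self.t_high}": self.frac_above_high,
        }


def compute_histogram(labeled: LabeledVolume) -> HUHistogram:
    """Count every non-background voxel by exact HU value."""
    values = labeled.data[labeled.foreground]
    if values.size == 0:
        return HUHistogram({})
    hu, counts = np.unique(values, return_counts=True)
    return HUHistogram({int(h): int(c) for h, c in zip(hu, counts)})


def frac_below(hist: HUHistogram, threshold: int) -> float:
    """Fraction of voxels with HU strictly below ``threshold`` (0 if empty)."""
    total = hist.total
    if total == 0:
        return 0.0
    return sum(c for h, c in hist.counts.items() if h < threshold) / total


def frac_above(hist: HUHistogram, threshold: int) -> float:
    """Fraction of voxels with HU strictly above ``threshold`` (0 if empty)."""
    total = hist.total
    if total == 0:
        return 0.0
    return sum(c for h, c in hist.counts.items() if h > threshold) / total


def modal_bin(hist: HUHistogram, bin_width: int = 100) -> tuple[int, int] | None:
    """Left-closed bin [b, b+width) with maximal count; lowest bin wins ties.

    Bin edges are aligned to multiples of ``bin_width``.
    """
    if hist.total == 0:
        return None
    sums: dict[int, int] = {}
    for h, c in hist.counts.items():
        b = (h // bin_width) * bin_width
        sums[b] = sums.get(b, 0) + c
    best = min(sorted(sums), key=lambda b: (-sums[b], b))
    return (best, best + bin_width)


def histogram_report(
    hist: HUHistogram,
    bin_width: int = 100,
    t_low: int = -950,
    t_high: int = -200,
) -> HistogramReport:
    """Compute modal bin and attenuation fractions for phenotype reading."""
    return HistogramReport(
        total=hist.total,
        modal_bin=modal_bin(hist, bin_width),
        frac_below_low=frac_below(hist, t_low),
        frac_above_high=frac_above(hist, t_high),
        t_low=t_low,
        t_high=t_high,
        bin_width=bin_width,
    )


def write_histogram_csv(hist: HUHistogram, path: str | os.PathLike) -> None:
    """Write ``hu,count`` rows in ascending HU order (sparse; no gap filling)."""
    with open(os.fspath(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["hu", "count"])
        for h in sorted(hist.counts):
            writer.writerow([h, hist.counts[h]])


def read_histogram_csv(path: str | os.PathLike) -> HUHistogram:
    """Inverse of :func:`write_histogram_csv`."""
    counts: dict[int, int] = {}
    with open(os.fspath(path), newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["hu", "count"]:
            raise FormatError(f"unexpected histogram CSV header: {header}")
        for row in reader:
            counts[int(row[0])] = int(row[1])
    return HUHistogram(counts)


def plot_histogram(hist: HUHistogram, ax=None, bin_width: int = 10):
    """Bar plot of the HU distribution (display binning only; data stay exact)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if hist.total:
        edges: dict[int, int] = {}
        for h, c in hist.counts.items():
            b = (h // bin_width) * bin_width
            edges[b] = edges.get(b, 0) + c
        xs = sorted(edges)
        ax.bar(xs, [edges[x] for x in xs], width=bin_width, align="edge")
    ax.set_xlabel("HU")
    ax.set_ylabel("voxel count")
    return ax
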