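"""Container for multivariate time series with optional epoch/label annotations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MultivariateTimeSeries:
    """A T x M matrix of samples with time stamps and per-sample annotations.

    Parameters
    ----------
    X : ndarray of shape (T, M)
        Samples; rows are time points, columns are channels/ROIs.
    times : ndarray of shape (T,)
        Time stamps in seconds.
    epochs : ndarray of shape (T,), optional
        Per-sample epoch/run identifier. Epochs must form contiguous runs;
        temporal adjacency is only meaningful within an epoch.
    labels : ndarray of shape (T,), optional
        Per-sample task/annotation strings.
    channel_names : list of str, optional
    """

    X: np.ndarray
    times: np.ndarray
    epochs: np.ndarray | None = None
    labels: np.ndarray | None = None
    channel_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D array (T x M)")
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.shape[0] != self.X.shape[0]:
            raise ValueError("times length must match number of rows of X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if self.epochs is None:
            self.epochs = np.zeros(self.X.shape[0], dtype=int)
        else:
            self.epochs = np.asarray(self.epochs).ravel()
            if self.epochs.shape[0] != self.X.shape[0]:
                raise ValueError("epochs length must match number of rows of X")
            # epochs must partition [0..T) into contiguous runs
            change = np.flatnonzero(self.epochs[1:] != self.epochs[:-1])
            seen: set = set()
            prev = None
            for e in self.epochs:
                if e != prev:
                    if e in seen:
                        raise ValueError(
                            "epoch labels must form contiguous runs; "
                            f"epoch {e!r} appears in disjoint segments"
                        )
                    seen.add(e)
                    prev = e
            del change
        if self.labels is not None:
            self.labels = np.asarray(self.labels).ravel()
            if self.labels.shape[0] != self.X.shape[0]:
                raise ValueError("labels length must match number of rows of X")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def epoch_slices(self) -> list[slice]:
        """Contiguous index ranges, one per epoch, in temporal order."""
        e = self.epochs
        bounds = np.flatnonzero(e[1:] != e[:-1]) + 1
        starts = np.concatenate(([0], bounds))
        stops = np.concatenate((bounds, [len(e)]))
        return [slice(int(a), int(b)) for a, b in zip(starts, stops)]
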