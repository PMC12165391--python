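"""Result containers with meta-species query access and per-time summaries."""

from __future__ import annotations

import json

import numpy as np

from .errors import SimulationError
from .model import MetaSpecies, Query


def _resample_hold(t_ref: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Previous-value (step) interpolation of ``y(t)`` onto ``t_ref``."""
    idx = np.searchsorted(t, t_ref, side="right") - 1
    idx = np.clip(idx, 0, len(t) - 1)
    return y[idx]


class Trajectory:
    """One run: a time grid, per-species series, and phase-boundary markers."""

    def __init__(self, time: np.ndarray, amounts: dict[str, np.ndarray],
                 boundaries: list[float]):
        self.time = time
        self.amounts = amounts
        self.boundaries = boundaries

    @property
    def end_time(self) -> float:
        return float(self.time[-1])

    def final_state(self) -> dict[str, float]:
        return {name: float(series[-1]) for name, series in self.amounts.items()}


class ResultSet:
    """Per-run trajectories; indexing by meta-species or query sums all
    matching concrete species, so no observables need declaring up front."""

    def __init__(self, trajectories: list[Trajectory],
                 simulated: list[MetaSpecies], species_names: list[str]):
        self.trajectories = trajectories
        self.simulated = simulated
        self.species_names = species_names

    def __len__(self):
        return len(self.trajectories)

    # -- query access ----------------------------------------------------------

    def _resolve(self, query) -> list[str]:
        if isinstance(query, str):
            if query not in self.species_names:
                raise SimulationError(f"unknown species {query!r}")
            return [query]
        if isinstance(query, MetaSpecies):
            query = query._as_query()
        if not isinstance(query, Query):
            raise SimulationError(f"cannot query results with {query!r}")
        names = [s.name for meta in self.simulated
                 if meta.descends_from(query.meta)
                 for s in meta.states() if query.matches(s)]
        if not names:
            raise SimulationError(f"query {query.label} matches no simulated species")
        return names

    def __getitem__(self, query) -> list[np.ndarray]:
        """Per-run summed series over the species matching ``query``."""
        names = self._resolve(query)
        return [sum(tr.amounts[n] for n in names) for tr in self.trajectories]

    def times(self) -> list[np.ndarray]:
        return [tr.time for tr in self.trajectories]

    def final(self, query) -> list[float]:
        return [float(series[-1]) for series in self[query]]

    # -- summaries ----------------------------------------------------------------

    def _reference_time(self) -> np.ndarray:
        return max((tr.time for tr in self.trajectories), key=lambda t: t[-1])

    def mean(self, query):
        """(time, mean) of the summed query series across runs, on the grid of
        the longest run; shorter runs hold their final value."""
        t_ref = self._reference_time()
        stack = np.vstack([_resample_hold(t_ref, tr.time, series)
                           for tr, series in zip(self.trajectories, self[query])])
        return t_ref, stack.mean(axis=0)

    def sd(self, query):
        t_ref = self._reference_time()
        stack = np.vstack([_resample_hold(t_ref, tr.time, series)
                           for tr, series in zip(self.trajectories, self[query])])
        return t_ref, stack.std(axis=0, ddof=1 if len(stack) > 1 else 0)

    # -- export ----------------------------------------------------------------

    def to_dataframe(self):
        """Tidy table with columns run, phase, time, species, amount."""
        import pandas as pd
        rows = []
        for run, tr in enumerate(self.trajectories):
            inner = np.asarray(tr.boundaries[1:-1])
            phase = np.searchsorted(inner, tr.time, side="right")
            for name, series in tr.amounts.items():
                for i, t in enumerate(tr.time):
                    rows.append((run, int(phase[i]), float(t), name,
                                 float(series[i])))
        return pd.DataFrame(rows, columns=["run", "phase", "time", "species",
                                           "amount"])

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path=None):
        """Mean/sd summaries per species as a JSON document."""
        doc = {}
        for name in self.species_names:
            t, m = self.mean(name)
            _, s = self.sd(name)
            doc[name] = {"time": t.tolist(), "mean": m.tolist(), "sd": s.tolist()}
        if path is None:
            return json.dumps(doc)
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return None


class SweepResults:
    """Factorial parameter sweep results keyed by full parameter assignment."""

    def __init__(self):
        self._cells: dict[tuple, ResultSet] = {}

    @staticmethod
    def _key(assignment) -> tuple:
        if isinstance(assignment, dict):
            assignment = assignment.items()
        return tuple(sorted(assignment, key=lambda kv: kv[0]))

    def add(self, assignment, results: ResultSet):
        self._cells[self._key(assignment)] = results

    def __getitem__(self, assignment) -> ResultSet:
        return self._cells[self._key(assignment)]

    def __iter__(self):
        return iter(self._cells.items())

    def __len__(self):
        return len(self._cells)

    @property
    def assignments(self) -> list[tuple]:
        return list(self._cells.keys())
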