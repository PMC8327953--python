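"""Trajectory-conditioned structured coalescent for the sweep phase.

Simulates the genealogy of a sample from a single Wright-Fisher population
of constant diploid size N backward through a per-generation allele
frequency trajectory at one selected site.  Lineages are partitioned into
the favoured (beneficial-allele) and background classes; each backward
generation every lineage picks a parent chromosome uniformly within its
class (so multiple mergers arise naturally when the class is small), and
recombination detaches the part of a lineage's material on the far side of
a breakpoint from the sweep site, re-assigning it to the favoured class
with probability equal to the current allele frequency.  In the final
trajectory generation the favoured class holds a single copy — the
mutation's origin haplotype — onto which all remaining favoured lineages
coalesce.

The result is a partially coalesced tskit table collection whose roots are
the lineages extant at the end of the trajectory; coalescence is finished
by a neutral continuation (msprime ``initial_state``).  This mirrors the
construction used by trajectory-conditioned sweep simulators: crucially,
soft sweeps from standing variation include the neutral drift phase of the
trajectory, during which carriers keep coalescing toward the single
mutational origin.

Times are in generations; positions in continuous [0, L) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tskit


@dataclass
class _Lineage:
    node: int
    segments: list  # disjoint (left, right) tuples, ascending
    favoured: bool

    @property
    def hull(self) -> tuple[float, float]:
        return self.segments[0][0], self.segments[-1][1]


def _split_segments(segments, breakpoint):
    left, right = [], []
    for lo, hi in segments:
        if hi <= breakpoint:
            left.append((lo, hi))
        elif lo >= breakpoint:
            right.append((lo, hi))
        else:
            left.append((lo, breakpoint))
            right.append((breakpoint, hi))
    return left, right


class SweepGenealogy:
    """Backward-in-time builder for the sweep-phase genealogy."""

    def __init__(self, n_samples, sequence_length, recombination_rate,
                 n_diploid, sweep_position, rng, population_name="stage"):
        self.L = float(sequence_length)
        self.r = float(recombination_rate)
        self.two_n = int(round(2 * n_diploid))
        self.pos = float(sweep_position)
        self.rng = rng
        self.n_samples = n_samples
        self.tables = tskit.TableCollection(sequence_length=self.L)
        self.tables.time_units = "generations"
        self.tables.populations.metadata_schema = tskit.MetadataSchema.permissive_json()
        self.tables.populations.add_row(
            metadata={"name": population_name, "description": ""}
        )

    def _new_node(self, time, flags=0):
        return self.tables.nodes.add_row(flags=flags, time=time, population=0)

    def _coalesce(self, lineages, time):
        """Merge two or more lineages into a new parent lineage."""
        parent = self._new_node(time)
        segments = []
        for lin in lineages:
            for lo, hi in lin.segments:
                self.tables.edges.add_row(
                    left=lo, right=hi, parent=parent, child=lin.node
                )
                segments.append((lo, hi))
        segments.sort()
        merged = [list(segments[0])]
        for lo, hi in segments[1:]:
            if lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        return _Lineage(
            node=parent,
            segments=[tuple(s) for s in merged],
            favoured=lineages[0].favoured,
        )

    def run(self, trajectory, max_time=None):
        """Run the structured phase conditioned on a frequency path.

        Parameters
        ----------
        trajectory
            Forward-time frequency path (origin .. sampling) from
            :func:`hapscan.simulate.sample_trajectory`.
        max_time
            Optional cap (generations) on the structured phase; if the
            trajectory is longer, remaining favoured lineages are released
            into the background unmerged (the continuation treats them
            neutrally).

        Returns ``(tables, carrier_flags, end_time)`` where carrier_flags
        marks the sample haplotypes drawn to carry the beneficial allele.
        """
        rng = self.rng
        x_sample = trajectory[-1]
        carriers = rng.random(self.n_samples) < x_sample
        if not carriers.any():
            carriers[rng.integers(self.n_samples)] = True

        lineages = []
        for i in range(self.n_samples):
            self._new_node(0.0, flags=tskit.NODE_IS_SAMPLE)
            lineages.append(
                _Lineage(node=i, segments=[(0.0, self.L)],
                         favoured=bool(carriers[i]))
            )

        T = len(trajectory) - 1
        capped = max_time is not None and T > max_time
        horizon = min(T, max_time) if capped else T
        tau = 0
        for tau in range(1, horizon + 1):
            x = trajectory[T - tau]  # frequency in the parent generation
            k_fav = min(self.two_n - 1, max(1, int(round(x * self.two_n))))
            k_bg = self.two_n - k_fav

            # recombination: each meiosis may split the lineage's material;
            # the piece on the far side of the sweep site re-draws its class
            new_lineages = []
            for lin in lineages:
                lo, hi = lin.hull
                span = hi - lo
                if span > 0 and rng.random() < -np.expm1(-self.r * span):
                    bp = lo + rng.random() * span
                    left, right = _split_segments(lin.segments, bp)
                    if left and right:
                        if self.pos < bp:
                            keep, other = left, right
                        else:
                            keep, other = right, left
                        new_lineages.append(
                            _Lineage(lin.node, keep, lin.favoured)
                        )
                        new_lineages.append(
                            _Lineage(lin.node, other, bool(rng.random() < x))
                        )
                        continue
                new_lineages.append(lin)

            # parent choice within each allelic class; lineages drawing the
            # same parent copy coalesce (multiple mergers possible)
            buckets: dict[tuple[bool, int], list[_Lineage]] = {}
            for lin in new_lineages:
                k = k_fav if lin.favoured else k_bg
                parent_copy = int(rng.integers(k))
                buckets.setdefault((lin.favoured, parent_copy), []).append(lin)
            lineages = []
            for group in buckets.values():
                if len(group) == 1:
                    lineages.append(group[0])
                else:
                    lineages.append(self._coalesce(group, float(tau)))

        if not capped:
            # the mutation arose on a single haplotype one generation
            # before the trajectory start
            fav = [lin for lin in lineages if lin.favoured]
            if len(fav) > 1:
                merged = self._coalesce(fav, float(tau + 1))
                lineages = [l for l in lineages if not l.favoured] + [merged]
        end_time = float(tau + 1)
        self.tables.sort()
        return self.tables, carriers, end_time
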