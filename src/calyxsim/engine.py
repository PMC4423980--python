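"""Particle-based stochastic reaction-diffusion core.

Each trial tracks every Ca2+ ion that enters through a channel: Brownian
motion with reflection at the compartment walls, the membrane, and the 45 nm
docked-vesicle spheres; binding to soluble buffers; and binding to the
five-site fusion sensor at each vesicle's membrane-proximal pole.  Fusion
removes the vesicle's sensor from further reaction.

Numerical scheme
----------------
* Soluble buffers are pseudo-first-order partners: they are far in excess of
  peak local Ca2+, so a free ion binds species b at rate k_on,b * [B_free,b](t)
  with the binding time sampled exactly from the exponential distribution (no
  encounter-radius calibration error), is parked event-driven for an
  Exp(k_off) sojourn, and re-emitted displaced by the Gaussian the buffer
  molecule would have diffused.  This is exact in the well-mixed limit and
  conserves every species by construction.
* The sensor is the spatially localised reaction: a free ion inside the
  capture pocket at the vesicle-membrane contact point binds a free site at
  rate (5-j) * k_on * c_ion, where c_ion is the concentration one ion
  represents in the pocket volume, so the well-mixed mass-action limit is
  recovered exactly.
* Near an obstacle the fine time step obeys rms step <= 1/4 vesicle radius.
  Away from obstacles free flights are event-driven: the ion takes a single
  Gaussian step to its next binding event or to a flight horizon chosen so
  the rms 3-D displacement stays below half the distance to the nearest
  vesicle surface (flat-wall reflection of a Gaussian increment is exact by
  the method of images, so only curved obstacles constrain the step).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .azmap import ActiveZoneMap
from .biophysics import (
    APWaveform,
    ChannelCurrentParams,
    GatingParams,
    GatingTrace,
    sample_gating,
    sample_ion_injections,
)
from .config import IONS_PER_NM3_PER_UM, SimConfig
from .placement import ChannelLayout


class StabilityError(RuntimeError):
    """Raised when the time step violates the stability criteria."""


def sensor_pocket_volume_nm3(
    rho_nm: float, r_ves_nm: float, shell_nm: float = 10.0, gap_nm: float = 5.0
) -> float:
    """Accessible volume of the capture pocket of a docked vesicle.

    The docked vesicle hovers ``gap_nm`` above the membrane (the EM docking
    criterion is a membrane distance of 10 nm or less).  The sensor sits on
    the vesicle surface facing the membrane; its capture pocket is the
    cytosolic region within ``rho`` of the membrane point below the vesicle
    centre, within ``shell`` of the sphere surface, above the membrane and
    outside the sphere.  Computed by 2-D quadrature in cylindrical
    coordinates.
    """
    zc = r_ves_nm + gap_nm
    s = np.linspace(0, rho_nm, 801)[1:]
    z = np.linspace(0, rho_nm, 801)[1:]
    S, Z = np.meshgrid(s, z, indexing="ij")
    pole2 = S**2 + Z**2
    cen2 = S**2 + (Z - zc) ** 2
    ok = (pole2 < rho_nm**2) & (cen2 > r_ves_nm**2) & (
        cen2 < (r_ves_nm + shell_nm) ** 2
    )
    ds = s[1] - s[0]
    dz = z[1] - z[0]
    return float(np.sum(2 * np.pi * S * ok) * ds * dz)


STATE_UNBORN = -1
STATE_FREE = 0
# 1 + s    : bound to buffer species s
# 1000 + v : bound to (or sequestered in) the sensor of vesicle v


@njit(cache=True)
def _inside_any(x, y, z, ves_xy, r_ves, z_c):
    """True if the point lies inside any vesicle sphere (centres at height z_c)."""
    for v in range(ves_xy.shape[0]):
        dxv = x - ves_xy[v, 0]
        dyv = y - ves_xy[v, 1]
        dzv = z - z_c
        if dxv * dxv + dyv * dyv + dzv * dzv < r_ves * r_ves:
            return True
    return False


@njit(cache=True, fastmath=True)
def _run_kernel(
    rng,
    n_steps,
    dt,
    hx,
    hy,
    box_h,
    d_ca,
    flight_tau_per_nm2,  # tau_max = flight_tau_per_nm2 * d_safe^2 (ms)
    max_flight_steps,
    ves_xy,
    r_ves,
    z_c,  # height of the sphere centres: r_ves + docking gap
    rho,
    r_out2,  # (r_ves + capture shell)^2: outer bound of the pocket
    p_capture,  # (6,) per-occupancy capture probability per fine step
    p_unbind,  # (6,) per-occupancy unbind probability per fine step
    p_fuse,
    kon_b,
    koff_b,
    btot,
    d_b,
    ions_per_uM,
    inj_t,
    inj_x,
    inj_y,
    init_pos,
    early_stop_all_fused,
    rec_stride,
    n_rec,
    trace_radius,
    snap_steps,
    map_bin,
    map_slab,
    nx,
    ny,
    ves_reflect_buffers,
):
    n_inj = inj_t.shape[0]
    n_init = init_pos.shape[0]
    n_cap = n_inj + n_init
    nv = ves_xy.shape[0]
    nb = kon_b.shape[0]

    pos = np.zeros((n_cap, 3))
    state = np.full(n_cap, STATE_UNBORN, dtype=np.int64)
    next_move = np.zeros(n_cap, dtype=np.int64)
    bind_step = np.zeros(n_cap, dtype=np.int64)

    # due-step schedule for free-ion moves: O(1) per visit, no scanning
    mv_head = np.full(n_steps + 2, -1, dtype=np.int64)
    mv_next = np.full(n_cap, -1, dtype=np.int64)

    ub_head = np.full(n_steps + 1, -1, dtype=np.int64)
    ub_next = np.full(n_cap, -1, dtype=np.int64)

    n_bound = np.zeros(nb, dtype=np.int64)
    occupancy = np.zeros(nv, dtype=np.int64)
    sens_ions = np.full((nv, 5), -1, dtype=np.int64)
    fused = np.zeros(nv, dtype=np.int64)
    fusion_times = np.full(nv, -1.0)
    n_sensor = 0
    n_free = 0
    n_injected = 0
    n_born = 0

    two_d = 2.0 * d_ca
    z_check = z_c + r_ves + 5.0  # vesicle collision checks only below this
    near_margin = 4.0 * np.sqrt(two_d * dt)  # fine stepping inside this clearance

    timeline = np.zeros((n_rec, 3 + nb), dtype=np.int64)
    traces = np.zeros((n_rec if trace_radius > 0 else 0, nv), dtype=np.int32)
    snaps = np.zeros((snap_steps.shape[0], nx, ny), dtype=np.int32)
    n_snap = snap_steps.shape[0]

    inj_ptr = 0
    snap_ptr = 0
    rec_ptr = 0
    all_done_step = n_steps

    for k in range(n_steps):
        t_now = k * dt
        t_next = t_now + dt

        # -- births ---------------------------------------------------------
        while inj_ptr < n_inj and inj_t[inj_ptr] < t_next:
            i = inj_ptr
            pos[i, 0] = inj_x[i]
            pos[i, 1] = inj_y[i]
            pos[i, 2] = 0.5
            state[i] = STATE_FREE
            next_move[i] = k + 1
            mv_next[i] = mv_head[k + 1]
            mv_head[k + 1] = i
            n_free += 1
            n_injected += 1
            n_born += 1
            inj_ptr += 1
        if k == 0:
            for j in range(n_init):
                i = n_inj + j
                pos[i, 0] = init_pos[j, 0]
                pos[i, 1] = init_pos[j, 1]
                pos[i, 2] = init_pos[j, 2]
                state[i] = STATE_FREE
                next_move[i] = 1
                mv_next[i] = mv_head[1]
                mv_head[1] = i
                n_free += 1
                n_injected += 1
                n_born += 1

        # -- scheduled buffer unbinding ---------------------------------------
        i = ub_head[k]
        while i >= 0:
            nxt = ub_next[i]
            s = state[i] - 1
            n_bound[s] -= 1
            if d_b[s] > 0.0:
                tau = (k - bind_step[i]) * dt
                sd = np.sqrt(2.0 * d_b[s] * tau)
                x = pos[i, 0] + sd * rng.standard_normal()
                y = pos[i, 1] + sd * rng.standard_normal()
                z = pos[i, 2] + sd * rng.standard_normal()
                while x < -hx or x > hx:
                    x = -2.0 * hx - x if x < -hx else 2.0 * hx - x
                while y < -hy or y > hy:
                    y = -2.0 * hy - y if y < -hy else 2.0 * hy - y
                while z < 0.0 or z > box_h:
                    z = -z if z < 0.0 else 2.0 * box_h - z
                if not (
                    ves_reflect_buffers
                    and z < z_check
                    and nv > 0
                    and _inside_any(x, y, z, ves_xy, r_ves, z_c)
                ):
                    pos[i, 0] = x
                    pos[i, 1] = y
                    pos[i, 2] = z
            state[i] = STATE_FREE
            next_move[i] = k + 1
            mv_next[i] = mv_head[k + 1]
            mv_head[k + 1] = i
            n_free += 1
            i = nxt

        # -- total buffer-binding rate this step ------------------------------
        r_tot = 0.0
        for s in range(nb):
            bf = btot[s] - n_bound[s] / ions_per_uM
            if bf > 0.0:
                r_tot += kon_b[s] * bf

        # flight horizon may not cross the next recording boundary while
        # position-dependent recording is pending
        flight_cap = max_flight_steps
        if trace_radius > 0:
            cap = rec_stride - (k % rec_stride)
            if cap < flight_cap:
                flight_cap = cap
        if snap_ptr < n_snap:
            sidx = snap_ptr
            if snap_steps[sidx] == k and sidx + 1 < n_snap:
                sidx += 1  # this step's snapshot is taken after the moves
            cap = snap_steps[sidx] - k
            if 0 < cap < flight_cap:
                flight_cap = cap

        # -- free-ion moves due this step -------------------------------------
        i = mv_head[k]
        mv_head[k] = -1
        while i >= 0:
            nxt_i = mv_next[i]
            if state[i] != STATE_FREE or next_move[i] != k:
                i = nxt_i  # stale entry: ion was bound or rescheduled
                continue
            x = pos[i, 0]
            y = pos[i, 1]
            z = pos[i, 2]

            # clearance to the nearest vesicle sphere; the height above the
            # obstacle layer is a free lower bound that spares the loop for
            # ions riding high in the box
            d2pole_min = 1e30
            if nv > 0:
                d_safe = z - (z_c + r_ves)
                if d_safe < 30.0:
                    d2min = 1e30
                    z2 = z * z
                    for v in range(nv):
                        dxv = x - ves_xy[v, 0]
                        dyv = y - ves_xy[v, 1]
                        dzv = z - z_c
                        dxy2 = dxv * dxv + dyv * dyv
                        d2 = dxy2 + dzv * dzv
                        if d2 < d2min:
                            d2min = d2
                        if dxy2 + z2 < d2pole_min:
                            d2pole_min = dxy2 + z2
                    d_safe = np.sqrt(d2min) - r_ves
            else:
                d_safe = 1e9

            if d_safe <= near_margin:
                pocket_gate = (rho + 4.0) * (rho + 4.0)
                L = flight_cap if flight_cap < 16 else 16
                if L > n_steps - k:
                    L = n_steps - k
                if L >= 2 and d2pole_min > pocket_gate:
                    # inner fine-stepping: identical per-step semantics
                    # (rejection at spheres, exact exponential binding) but
                    # without per-visit scheduling overhead; breaks as soon
                    # as the ion nears a sensor pocket so hazards are always
                    # applied by the per-step path
                    if r_tot > 0.0:
                        t_b = rng.standard_exponential() / r_tot
                        steps_to_bind = int(t_b / dt) + 1
                    else:
                        steps_to_bind = n_steps + 2
                    sigf = np.sqrt(two_d * dt)
                    j = 0
                    did_bind = False
                    while j < L:
                        nx_ = x + sigf * rng.standard_normal()
                        ny_ = y + sigf * rng.standard_normal()
                        nz_ = z + sigf * rng.standard_normal()
                        if nx_ < -hx or nx_ > hx:
                            nx_ = -2.0 * hx - nx_ if nx_ < -hx else 2.0 * hx - nx_
                        if ny_ < -hy or ny_ > hy:
                            ny_ = -2.0 * hy - ny_ if ny_ < -hy else 2.0 * hy - ny_
                        if nz_ < 0.0:
                            nz_ = -nz_
                        elif nz_ > box_h:
                            nz_ = 2.0 * box_h - nz_
                        inside = False
                        near_pocket = False
                        if nz_ < z_check:
                            nz2 = nz_ * nz_
                            for v in range(nv):
                                dxv = nx_ - ves_xy[v, 0]
                                dyv = ny_ - ves_xy[v, 1]
                                dzv = nz_ - z_c
                                dxy2 = dxv * dxv + dyv * dyv
                                if dxy2 + dzv * dzv < r_ves * r_ves:
                                    inside = True
                                    break
                                if dxy2 + nz2 < pocket_gate:
                                    near_pocket = True
                        if not inside:
                            x = nx_
                            y = ny_
                            z = nz_
                        j += 1
                        if j >= steps_to_bind:
                            did_bind = True
                            break
                        if near_pocket:
                            break
                    pos[i, 0] = x
                    pos[i, 1] = y
                    pos[i, 2] = z
                    if did_bind:
                        u = rng.random() * r_tot
                        acc = 0.0
                        chosen = nb - 1
                        for s in range(nb):
                            bf = btot[s] - n_bound[s] / ions_per_uM
                            if bf > 0.0:
                                acc += kon_b[s] * bf
                            if u <= acc:
                                chosen = s
                                break
                        kb = k + j
                        state[i] = 1 + chosen
                        n_bound[chosen] += 1
                        n_free -= 1
                        bind_step[i] = kb
                        if koff_b[chosen] > 0.0:
                            dwell = rng.standard_exponential() / koff_b[chosen]
                            ks = kb + 1 + int(dwell / dt)
                        else:
                            ks = n_steps + 1
                        if ks <= n_steps - 1:
                            ub_next[i] = ub_head[ks]
                            ub_head[ks] = i
                        i = nxt_i
                        continue
                    km = k + j
                    if km <= k:
                        km = k + 1
                    # the landed position must receive the same sensor check
                    # as a single-step move would, or pocket entries lose
                    # their first in-pocket step of hazard; pocket dwellers
                    # are re-examined every step
                    if z < rho:
                        km = k + 1
                        took = False
                        for v in range(nv):
                            if fused[v] == 1 or occupancy[v] >= 5:
                                continue
                            dxv = x - ves_xy[v, 0]
                            if dxv > rho or dxv < -rho:
                                continue
                            dyv = y - ves_xy[v, 1]
                            dzv = z - z_c
                            if (
                                dxv * dxv + dyv * dyv + z * z < rho * rho
                                and dxv * dxv + dyv * dyv + dzv * dzv < r_out2
                            ):
                                if rng.random() < p_capture[occupancy[v]]:
                                    sens_ions[v, occupancy[v]] = i
                                    occupancy[v] += 1
                                    state[i] = 1000 + v
                                    n_sensor += 1
                                    n_free -= 1
                                    took = True
                                    break
                        if took:
                            i = nxt_i
                            continue
                    if km > n_steps:
                        km = n_steps
                    next_move[i] = km
                    mv_next[i] = mv_head[km]
                    mv_head[km] = i
                    i = nxt_i
                    continue
                m = 1
            else:
                m = int(flight_tau_per_nm2 * d_safe * d_safe / dt)
                if m < 1:
                    m = 1
                elif m > flight_cap:
                    m = flight_cap
            if m > n_steps - k:
                m = n_steps - k
                if m < 1:
                    m = 1

            # exact exponential binding time
            bound_now = False
            if r_tot > 0.0:
                t_b = rng.standard_exponential() / r_tot
                if t_b < m * dt:
                    mb = int(t_b / dt)
                    sd = np.sqrt(two_d * t_b) if t_b > 0.0 else 0.0
                    bound_now = True
                    m = mb if mb > 0 else 1
            if not bound_now:
                sd = np.sqrt(two_d * (m * dt))

            x += sd * rng.standard_normal()
            y += sd * rng.standard_normal()
            z += sd * rng.standard_normal()
            while x < -hx or x > hx:
                x = -2.0 * hx - x if x < -hx else 2.0 * hx - x
            while y < -hy or y > hy:
                y = -2.0 * hy - y if y < -hy else 2.0 * hy - y
            while z < 0.0 or z > box_h:
                z = -z if z < 0.0 else 2.0 * box_h - z
            if z < z_check and nv > 0 and _inside_any(x, y, z, ves_xy, r_ves, z_c):
                # reject the move (symmetric proposal into a reflective
                # obstacle): preserves the uniform equilibrium law exactly
                x = pos[i, 0]
                y = pos[i, 1]
                z = pos[i, 2]
            else:
                pos[i, 0] = x
                pos[i, 1] = y
                pos[i, 2] = z

            if bound_now:
                # pick the species proportionally to its current rate
                u = rng.random() * r_tot
                acc = 0.0
                chosen = nb - 1
                for s in range(nb):
                    bf = btot[s] - n_bound[s] / ions_per_uM
                    if bf > 0.0:
                        acc += kon_b[s] * bf
                    if u <= acc:
                        chosen = s
                        break
                kb = k + m
                state[i] = 1 + chosen
                n_bound[chosen] += 1
                n_free -= 1
                bind_step[i] = kb
                if koff_b[chosen] > 0.0:
                    dwell = rng.standard_exponential() / koff_b[chosen]
                    ks = kb + 1 + int(dwell / dt)
                else:
                    ks = n_steps + 1
                if ks <= n_steps - 1:
                    ub_next[i] = ub_head[ks]
                    ub_head[ks] = i
                i = nxt_i
                continue

            km = k + m
            # sensor binding: only possible inside the capture pocket.  The
            # hazard covers one fine step; ions that land near the membrane
            # after a long flight are re-examined next step so pocket dwell
            # is accounted per step, never per flight.
            if z < rho and nv > 0:
                if m > 1:
                    km = k + 1
                took = False
                for v in range(nv):
                    if fused[v] == 1 or occupancy[v] >= 5:
                        continue
                    dxv = x - ves_xy[v, 0]
                    if dxv > rho or dxv < -rho:
                        continue
                    dyv = y - ves_xy[v, 1]
                    dzv = z - z_c
                    if (
                        dxv * dxv + dyv * dyv + z * z < rho * rho
                        and dxv * dxv + dyv * dyv + dzv * dzv < r_out2
                    ):
                        if rng.random() < p_capture[occupancy[v]]:
                            sens_ions[v, occupancy[v]] = i
                            occupancy[v] += 1
                            state[i] = 1000 + v
                            n_sensor += 1
                            n_free -= 1
                            took = True
                            break
                if took:
                    i = nxt_i
                    continue
            if km > n_steps:
                km = n_steps
            next_move[i] = km
            mv_next[i] = mv_head[km]
            mv_head[km] = i
            i = nxt_i

        # -- sensor fusion / unbinding ----------------------------------------
        for v in range(nv):
            if fused[v] == 1:
                continue
            j = occupancy[v]
            if j == 5 and p_fuse > 0.0 and rng.random() < p_fuse:
                fused[v] = 1
                fusion_times[v] = t_next
                continue
            if j > 0 and rng.random() < p_unbind[j]:
                i = sens_ions[v, j - 1]
                sens_ions[v, j - 1] = -1
                occupancy[v] = j - 1
                n_sensor -= 1
                # re-emit uniformly in the capture pocket
                rx = 0.0
                ry = 0.0
                rz = 0.5
                for _try in range(256):
                    rx = (rng.random() * 2.0 - 1.0) * rho
                    ry = (rng.random() * 2.0 - 1.0) * rho
                    rz = rng.random() * rho
                    if rx * rx + ry * ry + rz * rz > rho * rho:
                        continue
                    dzv = rz - z_c
                    c2 = rx * rx + ry * ry + dzv * dzv
                    if c2 <= r_ves * r_ves or c2 >= r_out2:
                        continue
                    break
                pos[i, 0] = ves_xy[v, 0] + rx
                pos[i, 1] = ves_xy[v, 1] + ry
                pos[i, 2] = rz
                state[i] = STATE_FREE
                next_move[i] = k + 1
                mv_next[i] = mv_head[k + 1]
                mv_head[k + 1] = i
                n_free += 1

        # -- recording ---------------------------------------------------------
        if rec_stride > 0 and k % rec_stride == 0 and rec_ptr < n_rec:
            timeline[rec_ptr, 0] = n_injected
            timeline[rec_ptr, 1] = n_free
            timeline[rec_ptr, 2] = n_sensor
            for s in range(nb):
                timeline[rec_ptr, 3 + s] = n_bound[s]
            if trace_radius > 0:
                tr2 = trace_radius * trace_radius
                for i2 in range(n_born):
                    if state[i2] != STATE_FREE:
                        continue
                    if pos[i2, 2] > trace_radius:
                        continue
                    for v in range(nv):
                        dxv = pos[i2, 0] - ves_xy[v, 0]
                        dyv = pos[i2, 1] - ves_xy[v, 1]
                        if dxv * dxv + dyv * dyv + pos[i2, 2] * pos[i2, 2] < tr2:
                            traces[rec_ptr, v] += 1
            rec_ptr += 1
        if snap_ptr < n_snap and k == snap_steps[snap_ptr]:
            for i2 in range(n_born):
                if state[i2] != STATE_FREE:
                    continue
                if pos[i2, 2] < map_slab:
                    bx = int((pos[i2, 0] + hx) / map_bin)
                    by = int((pos[i2, 1] + hy) / map_bin)
                    if 0 <= bx < nx and 0 <= by < ny:
                        snaps[snap_ptr, bx, by] += 1
            snap_ptr += 1

        if early_stop_all_fused and nv > 0:
            done = True
            for v in range(nv):
                if fused[v] == 0:
                    done = False
                    break
            if done and inj_ptr >= n_inj:
                all_done_step = k + 1
                break

    return fusion_times, state, timeline, traces, snaps, pos, n_injected, all_done_step


# ---------------------------------------------------------------------------
# python-facing layer
# ---------------------------------------------------------------------------


@dataclass
class TrialResult:
    """One stochastic trial: gating, ion bookkeeping, fusion times."""

    fusion_times_ms: np.ndarray  # (n_vesicles,), nan where no fusion
    n_injected: int
    n_injections_scheduled: int  # full AP influx; equals n_injected unless the
    # trial stopped early after every vesicle had fused
    gating: list[GatingTrace]
    timeline_t_ms: np.ndarray
    timeline_counts: np.ndarray  # columns: injected, free, sensor-bound, per-buffer
    buffer_names: list[str]
    sensor_traces: np.ndarray | None = None  # (n_rec, n_vesicles) pocket counts
    map_snapshots: np.ndarray | None = None  # (n_snap, nx, ny) ion counts
    map_snapshot_times_ms: np.ndarray | None = None
    final_states: np.ndarray | None = None
    final_positions: np.ndarray | None = None
    stop_time_ms: float = 0.0
    config: SimConfig | None = None

    @property
    def n_fused(self) -> int:
        return int(np.sum(~np.isnan(self.fusion_times_ms)))

    def check_mass_conservation(self) -> None:
        """Free + buffer-bound + sensor-bound must equal injected at all times."""
        c = self.timeline_counts
        total = c[:, 1:].sum(axis=1)
        if not np.array_equal(total, c[:, 0]):
            raise AssertionError("Ca2+ mass conservation violated")


def _check_stability(cfg: SimConfig, r_obstacle_nm: float) -> None:
    d_ca = cfg.d_ca_um2_s * 1000.0  # nm^2/ms
    step = np.sqrt(2 * d_ca * cfg.dt_fine_ms)
    if r_obstacle_nm > 0 and step > r_obstacle_nm / 4:
        raise StabilityError(
            f"fine step rms {step:.2f} nm exceeds 1/4 obstacle radius "
            f"({r_obstacle_nm / 4:.2f} nm); reduce dt_fine_ms"
        )
    r_tot = sum(b.k_on_per_uM_ms * b.total_uM for b in cfg.buffers)
    if r_tot * cfg.dt_fine_ms > 0.2:
        raise StabilityError(
            f"buffer reaction probability per step {r_tot * cfg.dt_fine_ms:.2f} > 0.2"
        )


def run_trial(
    az: ActiveZoneMap,
    layout: ChannelLayout,
    cfg: SimConfig,
    stimulus: APWaveform,
    seed: int,
    *,
    duration_ms: float | None = None,
    early_stop_all_fused: bool = False,
    init_ion_positions: np.ndarray | None = None,
    record_final_positions: bool = False,
) -> TrialResult:
    """Run one stochastic trial of the full model.

    Gating is sampled per channel along the stimulus waveform, ion entry is an
    inhomogeneous Poisson process while open, and the particle kernel then
    propagates every ion.  ``duration_ms`` defaults to
    min(release window, last injection + 2 ms): after the free-Ca2+ transient
    has equilibrated into the buffers the residual fusion hazard is
    negligible (< 1e-3 of peak).
    """
    _check_stability(cfg, az.vesicle_radius if az.n_vesicles else 0.0)
    rng = np.random.default_rng(seed)
    gp = GatingParams(
        alpha0_per_ms=cfg.gating.alpha0_per_ms, k_alpha_mV=cfg.gating.k_alpha_mV,
        beta0_per_ms=cfg.gating.beta0_per_ms, k_beta_mV=cfg.gating.k_beta_mV,
    )
    cp = ChannelCurrentParams(
        i_at_0mV_pA=cfg.current.i_at_0mV_pA, reversal_mV=cfg.current.reversal_mV,
        mode=cfg.current.mode,
    )
    gating = sample_gating(stimulus, gp, layout.n_channels,
                           seed=int(rng.integers(2**31)))
    times_all, ch_all = [], []
    for c, tr in enumerate(gating):
        t = sample_ion_injections(tr, stimulus, cp, seed=rng)
        times_all.append(t)
        ch_all.append(np.full(len(t), c))
    inj_t = np.concatenate(times_all) if times_all else np.empty(0)
    inj_ch = np.concatenate(ch_all) if ch_all else np.empty(0, dtype=int)
    order = np.argsort(inj_t, kind="stable")
    inj_t, inj_ch = inj_t[order], inj_ch[order].astype(np.int64)
    inj_x = layout.positions[inj_ch, 0] if len(inj_t) else np.empty(0)
    inj_y = layout.positions[inj_ch, 1] if len(inj_t) else np.empty(0)

    if duration_ms is None:
        if len(inj_t):
            duration_ms = float(min(cfg.release_window_ms, inj_t[-1] + 2.0))
        else:
            duration_ms = min(cfg.release_window_ms, 0.25)
    dt = cfg.dt_fine_ms
    n_steps = int(np.ceil(duration_ms / dt))

    sp = cfg.sensor
    v_pocket = sensor_pocket_volume_nm3(
        sp.capture_radius_nm, az.vesicle_radius, sp.capture_shell_nm,
        cfg.dock_gap_nm,
    )
    conc_per_ion = 1.0 / (v_pocket * IONS_PER_NM3_PER_UM)
    # per-occupancy capture probability for one in-pocket ion and one fine
    # step, with the discrete-depletion (retry-time) correction so the
    # well-mixed mass-action rate is recovered (see calibrate_sensor_capture)
    jj5 = np.arange(6, dtype=float)
    hazard = np.clip(5 - jj5, 0, None) * sp.k_on_per_uM_ms * conc_per_ion
    h_eff = hazard * (1.0 + hazard * cfg.sensor_retry_time_ms)
    p_capture = 1.0 - np.exp(-h_eff * cfg.dt_fine_ms)
    jj = np.arange(6, dtype=float)
    unbind_rate = jj * sp.k_off_per_ms * sp.cooperativity_b ** np.clip(jj - 1, 0, None)
    p_unbind = 1.0 - np.exp(-unbind_rate * dt)
    p_fuse = 1.0 - np.exp(-sp.gamma_per_ms * dt)

    kon_b = np.array([b.k_on_per_uM_ms for b in cfg.buffers])
    koff_b = np.array([b.k_off_per_ms for b in cfg.buffers])
    btot = np.array([b.total_uM for b in cfg.buffers])
    d_b = np.array([b.d_um2_s * 1000.0 for b in cfg.buffers])  # nm^2/ms

    rec_stride = max(1, int(round(cfg.record.species_interval_ms / dt)))
    n_rec = n_steps // rec_stride + 1
    trace_radius = cfg.record.sensor_trace_radius_nm if cfg.record.sensor_ca_traces else 0.0
    snap_steps = np.array(
        sorted(int(round(t / dt)) for t in cfg.record.map_snapshot_times_ms),
        dtype=np.int64,
    )
    nx = int(np.ceil(cfg.box_x_nm / cfg.record.map_bin_nm))
    ny = int(np.ceil(cfg.box_y_nm / cfg.record.map_bin_nm))

    init_pos = (
        np.asarray(init_ion_positions, dtype=float).reshape(-1, 3)
        if init_ion_positions is not None
        else np.empty((0, 3))
    )

    d_ca_nm = cfg.d_ca_um2_s * 1000.0
    # rms 3-D flight displacement <= d_safe / safety_factor
    flight_tau_per_nm2 = 1.0 / (6.0 * d_ca_nm * cfg.flight_safety_factor**2) if d_ca_nm else 0.0

    out = _run_kernel(
        np.random.Generator(np.random.SFC64(int(rng.integers(2**31)))),
        n_steps,
        dt,
        cfg.box_x_nm / 2,
        cfg.box_y_nm / 2,
        cfg.box_z_nm,
        d_ca_nm,
        flight_tau_per_nm2,
        cfg.max_flight_steps,
        np.ascontiguousarray(az.vesicle_centres, dtype=np.float64).reshape(-1, 2),
        float(az.vesicle_radius),
        float(az.vesicle_radius + cfg.dock_gap_nm),
        float(sp.capture_radius_nm),
        float((az.vesicle_radius + sp.capture_shell_nm) ** 2),
        p_capture,
        p_unbind,
        p_fuse,
        kon_b,
        koff_b,
        btot,
        d_b,
        cfg.ions_per_uM(),
        inj_t,
        inj_x,
        inj_y,
        init_pos,
        early_stop_all_fused,
        rec_stride,
        n_rec,
        trace_radius,
        snap_steps,
        cfg.record.map_bin_nm,
        cfg.record.map_slab_nm,
        nx,
        ny,
        cfg.vesicles_reflect_buffers,
    )
    fusion_times, states, timeline, traces, snaps, pos, n_injected, stop_step = out
    fusion = np.where(fusion_times >= 0, fusion_times, np.nan)
    n_rec_actual = min(n_rec, stop_step // rec_stride + 1)
    return TrialResult(
        fusion_times_ms=fusion,
        n_injected=int(n_injected),
        n_injections_scheduled=len(inj_t),
        gating=gating,
        timeline_t_ms=np.arange(n_rec_actual) * rec_stride * dt,
        timeline_counts=timeline[:n_rec_actual],
        buffer_names=[b.name for b in cfg.buffers],
        sensor_traces=traces[:n_rec_actual] if trace_radius > 0 else None,
        map_snapshots=snaps if len(snap_steps) else None,
        map_snapshot_times_ms=snap_steps * dt if len(snap_steps) else None,
        final_states=states if record_final_positions else None,
        final_positions=pos if record_final_positions else None,
        stop_time_ms=float(stop_step * dt),
        config=cfg,
    )


def near_membrane_map(result: TrialResult, t_ms: float, bin_nm: float | None = None) -> np.ndarray:
    """Near-membrane free-[Ca2+] grid (uM) at a recorded snapshot time."""
    if result.map_snapshots is None:
        raise RuntimeError("map recording was not enabled for this trial")
    cfg = result.config
    times = result.map_snapshot_times_ms
    i = int(np.argmin(np.abs(times - t_ms)))
    if abs(times[i] - t_ms) > cfg.record.species_interval_ms + cfg.dt_fine_ms:
        raise ValueError(f"no snapshot recorded near t = {t_ms} ms")
    counts = result.map_snapshots[i].astype(float)
    vol = cfg.record.map_bin_nm**2 * cfg.record.map_slab_nm
    return counts / (vol * IONS_PER_NM3_PER_UM)


@dataclass
class ReleaseBatch:
    """Aggregate of repeated trials on one geometry."""

    n_trials: int
    n_vesicles: int
    fusion_counts: np.ndarray  # (n_vesicles,)
    fusion_times: list[np.ndarray]  # per vesicle, ms
    released_per_trial: np.ndarray  # (n_trials,)
    injected_per_trial: np.ndarray  # (n_trials,)
    stop_times_ms: np.ndarray

    @property
    def p_ves(self) -> np.ndarray:
        return self.fusion_counts / self.n_trials

    @property
    def mean_p_ves(self) -> float:
        return float(self.p_ves.mean()) if self.n_vesicles else 0.0

    @property
    def mean_ions(self) -> float:
        return float(self.injected_per_trial.mean())

    @property
    def failure_fraction(self) -> float:
        return float(np.mean(self.released_per_trial == 0))


def run_trials(
    az: ActiveZoneMap,
    layout: ChannelLayout,
    cfg: SimConfig,
    stimulus: APWaveform,
    n_trials: int,
    seed: int,
    **trial_kwargs,
) -> ReleaseBatch:
    """Run ``n_trials`` independent trials and aggregate release statistics."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(n_trials)]
    nv = az.n_vesicles
    counts = np.zeros(nv)
    ftimes: list[list[float]] = [[] for _ in range(nv)]
    released = np.zeros(n_trials, dtype=int)
    injected = np.zeros(n_trials, dtype=int)
    stops = np.zeros(n_trials)
    for i, s in enumerate(seeds):
        res = run_trial(az, layout, cfg, stimulus, s % 2**31, **trial_kwargs)
        isfused = ~np.isnan(res.fusion_times_ms)
        counts += isfused
        for v in np.flatnonzero(isfused):
            ftimes[v].append(res.fusion_times_ms[v])
        released[i] = isfused.sum()
        injected[i] = res.n_injections_scheduled
        stops[i] = res.stop_time_ms
    return ReleaseBatch(
        n_trials=n_trials,
        n_vesicles=nv,
        fusion_counts=counts,
        fusion_times=[np.sort(np.array(f)) for f in ftimes],
        released_per_trial=released,
        injected_per_trial=injected,
        stop_times_ms=stops,
    )
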