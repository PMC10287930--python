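"""The plate and plate-reader assay formulas on worked inputs."""

from focigap import (
    background_subtract,
    live_dead_percentage,
    plasmid_loss_fraction,
    sos_signal,
    tet_recombination_frequency,
)

# live/dead staining: 70 live, 30 dead cells in the field
print(f"dead cells: {live_dead_percentage(alive=70, dead=30):.1f} %")

# SOS reporter: fluorescence/OD of the reporter strain minus empty-vector control
print(f"SOS signal: {sos_signal(1000.0, 0.5, 200.0, 0.5):.0f} (a.u. per OD)")

# Tet recombination: 20 TetR/Amp colonies on the 1e-1 plate,
# 100 Amp colonies on the 1e-5 plate
f = tet_recombination_frequency(20, 100, tet_amp_dilution=1e-1, amp_dilution=1e-5)
print(f"Tet recombination frequency: {f:.4f} %")

# plasmid loss: 90 blue (plasmid-bearing) vs 10 white colonies
frac, (lo, hi) = plasmid_loss_fraction(blue=90, white=10)
print(f"plasmid loss: {frac:.2f} (95% CI {lo:.3f}-{hi:.3f})")

# far-western dot blot: probe membrane 500 vs control membrane 100
print(f"background-subtracted blot signal: {background_subtract(500.0, 100.0).value:.0f}")
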