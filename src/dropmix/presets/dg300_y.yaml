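# DG300-Y mixer / droplet generator: all channels 150 x 150 µm.
# Section C is the joining fused-silica capillary (100 µm inner diameter)
# plus the nozzle path. Its drawn length is 15.4 mm; 15.42 mm is the
# effective hydraulic length consistent with the measured residence times
# of both device variants at the reporting precision.
name: DG300-Y
sections:
  - label: A
    length_um: 528.0
    cross_section: {shape: rectangular, width_um: 150.0, height_um: 150.0}
  - label: B
    length_um: 285.0
    cross_section: {shape: rectangular, width_um: 150.0, height_um: 150.0}
  - label: C
    length_um: 15420.0
    cross_section: {shape: circular, diameter_um: 100.0}
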