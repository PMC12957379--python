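# DG250-Y mixer / droplet generator: 100 x 100 µm aqueous mixing channel
# joining a 150 x 150 µm droplet-forming channel. Section C as for DG300-Y.
name: DG250-Y
sections:
  - label: A
    length_um: 528.0
    cross_section: {shape: rectangular, width_um: 100.0, height_um: 100.0}
  - label: B
    length_um: 285.0
    cross_section: {shape: rectangular, width_um: 150.0, height_um: 150.0}
  - label: C
    length_um: 15420.0
    cross_section: {shape: circular, diameter_um: 100.0}
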