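# Assay metadata specification: one common core shared by every assay,
# plus named per-assay extension categories. Fields describing
# reagent-independent experimental parameters.
family: assay
version: "1.0"
common_fields: []
categories:
  - name: Assay
    fields:
      - {name: Assay Name, importance: 1, value_kind: text,
         description: Official assay name, provenance: implementer-defined}
      - {name: Assay Type, importance: 1, value_kind: text,
         description: Broad assay class, provenance: implementer-defined}
      - {name: Assay Format, importance: 2, value_kind: text,
         description: Cell-based or biochemical format,
         provenance: implementer-defined}
      - {name: Detection Technology, importance: 2, value_kind: text,
         description: Signal detection technology, provenance: implementer-defined}
      - {name: Readout Type, importance: 2, value_kind: text,
         description: Nature of the measured readout,
         provenance: implementer-defined}
      - {name: Protocol Reference, importance: 2, value_kind: url,
         description: Link to the published assay protocol,
         provenance: implementer-defined}
      - {name: BAO ID, importance: 3, value_kind: identifier,
         description: BioAssay Ontology accession, provenance: implementer-defined}
      - {name: Instrument, importance: 3, value_kind: text,
         description: Instrument make and model, provenance: implementer-defined}
      - {name: Comments, importance: 3, value_kind: text,
         description: Free-text notes, provenance: implementer-defined}
  - name: L1000 extension
    fields:
      - {name: Landmark Gene Count, importance: 2, value_kind: integer,
         description: Number of directly measured landmark genes,
         provenance: implementer-defined}
      - {name: Bead Set, importance: 3, value_kind: text,
         description: Bead set identifier, provenance: implementer-defined}
  - name: P100 extension
    fields:
      - {name: Probe Count, importance: 2, value_kind: integer,
         description: Number of phosphopeptide probes,
         provenance: implementer-defined}
      - {name: Mass Spectrometer, importance: 3, value_kind: text,
         description: Instrument used for quantification,
         provenance: implementer-defined}
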