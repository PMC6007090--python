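# Experimental metadata specification: 6 categories describing the
# conditions under which each reagent class is applied. The five cell
# reagent categories (Cell lines, Primary cells, Differentiated cells,
# iPSCs, Embryonic stem cells) share the single experimental category
# "Cells".
family: experimental
version: "1.0"
common_fields:
  - {name: Experiment ID, importance: 1, value_kind: identifier,
     description: Center-assigned experiment identifier,
     provenance: implementer-defined}
  - {name: Reagent Batch ID, importance: 1, value_kind: identifier,
     description: Batch identifier of the reagent used,
     provenance: implementer-defined}
  - {name: Time Point, importance: 2, value_kind: decimal,
     description: Readout time after perturbation,
     provenance: implementer-defined}
  - {name: Time Point Unit, importance: 2, value_kind: vocabulary,
     vocabulary_ref: time_unit, description: Unit of the time point,
     provenance: implementer-defined}
  - {name: Replicate Number, importance: 3, value_kind: integer,
     description: Biological replicate index, provenance: implementer-defined}
  - {name: Comments, importance: 3, value_kind: text,
     description: Free-text notes, provenance: implementer-defined}
categories:
  - name: Small molecules
    fields:
      - {name: Concentration, importance: 1, value_kind: decimal,
         description: Treatment concentration, provenance: published}
      - {name: Concentration Unit, importance: 1, value_kind: vocabulary,
         vocabulary_ref: concentration_unit, description: Unit of concentration,
         provenance: implementer-defined}
      - {name: Vehicle, importance: 2, value_kind: text,
         description: Solvent vehicle, provenance: implementer-defined}
      - {name: Treatment Duration, importance: 2, value_kind: decimal,
         description: Exposure duration in hours, provenance: implementer-defined}
  - name: Cells
    fields:
      - {name: Cell Density, importance: 2, value_kind: decimal,
         description: Seeding density in cells per well, provenance: published}
      - {name: Culture Vessel, importance: 3, value_kind: text,
         description: Plate or flask format, provenance: implementer-defined}
      - {name: Passage Number, importance: 3, value_kind: integer,
         description: Passage at the time of the experiment,
         provenance: implementer-defined}
      - {name: Seeding Protocol, importance: 3, value_kind: text,
         description: Protocol reference for seeding, provenance: implementer-defined}
  - name: Proteins
    fields:
      - {name: Concentration, importance: 1, value_kind: decimal,
         description: Applied protein concentration, provenance: implementer-defined}
      - {name: Concentration Unit, importance: 1, value_kind: vocabulary,
         vocabulary_ref: concentration_unit, description: Unit of concentration,
         provenance: implementer-defined}
      - {name: Incubation Time, importance: 3, value_kind: decimal,
         description: Incubation time in hours, provenance: implementer-defined}
  - name: Antibody reagents
    fields:
      - {name: Dilution, importance: 1, value_kind: text,
         description: Working dilution, provenance: implementer-defined}
      - {name: Incubation Time, importance: 3, value_kind: decimal,
         description: Incubation time in hours, provenance: implementer-defined}
      - {name: Detection Method, importance: 3, value_kind: text,
         description: Secondary detection modality, provenance: implementer-defined}
  - name: Nucleic acid reagents
    fields:
      - {name: Concentration, importance: 1, value_kind: decimal,
         description: Transfection concentration, provenance: implementer-defined}
      - {name: Concentration Unit, importance: 1, value_kind: vocabulary,
         vocabulary_ref: concentration_unit, description: Unit of concentration,
         provenance: implementer-defined}
      - {name: Transfection Reagent, importance: 2, value_kind: text,
         description: Transfection chemistry used, provenance: implementer-defined}
      - {name: Transfection Duration, importance: 3, value_kind: decimal,
         description: Transfection duration in hours, provenance: implementer-defined}
  - name: Unclassified perturbagens
    fields:
      - {name: Dose, importance: 2, value_kind: decimal,
         description: Applied dose, provenance: implementer-defined}
      - {name: Dose Unit, importance: 2, value_kind: text,
         description: Unit of the dose, provenance: implementer-defined}
      - {name: Exposure Duration, importance: 3, value_kind: decimal,
         description: Exposure duration in hours, provenance: implementer-defined}
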