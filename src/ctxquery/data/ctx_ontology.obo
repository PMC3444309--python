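format-version: 1.2
ontology: ctx-phenotype-subset
remark: Hand-curated subset of a CTX (cerebrotendinous xanthomatosis) phenotype management ontology. Four is-a hierarchies: Phenotype, AnatomicalStructure, DiagnosticStudy, QualifierValue. The internal structure between named concepts is a curation choice of this package; subset tags record whether a concept is reused from HPO, from SNOMED CT, or newly created.
subsetdef: HPO-derived "concept reused from the Human Phenotype Ontology"
subsetdef: SNOMED-derived "concept reused from SNOMED CT"
subsetdef: new "newly created concept"

[Term]
id: Phenotype
name: Phenotype

[Term]
id: AbnormalityOfTheNervousSystem
name: Abnormality of the nervous system
is_a: Phenotype
subset: HPO-derived

[Term]
id: AbnormalityOfTheCentralNervousSystem
name: Abnormality of the central nervous system
is_a: AbnormalityOfTheNervousSystem
subset: HPO-derived

[Term]
id: SeizureDisorder
name: Seizure disorder
is_a: AbnormalityOfTheCentralNervousSystem
subset: HPO-derived

[Term]
id: Epilepsy
name: Epilepsy
is_a: SeizureDisorder
synonym: "epileptic seizures" EXACT []
synonym: "convulsions" RELATED []
subset: HPO-derived

[Term]
id: StructuralBrainAbnormality
name: Structural brain abnormality
is_a: AbnormalityOfTheCentralNervousSystem
subset: SNOMED-derived

[Term]
id: AbnormalityOfTheCerebellum
name: Abnormality of the cerebellum
is_a: AbnormalityOfTheCentralNervousSystem
subset: HPO-derived

[Term]
id: Ataxia
name: Ataxia
is_a: AbnormalityOfTheCerebellum
synonym: "cerebellar ataxia" RELATED []
subset: HPO-derived

[Term]
id: ArnoldChiariTypeI
name: Arnold-Chiari type I malformation
is_a: AbnormalityOfTheCerebellum
is_a: StructuralBrainAbnormality
synonym: "Chiari malformation type I" EXACT []
subset: SNOMED-derived

[Term]
id: CerebellarAtrophy
name: Cerebellar atrophy
is_a: AbnormalityOfTheCerebellum
subset: HPO-derived

[Term]
id: Dementia
name: Dementia
is_a: AbnormalityOfTheCentralNervousSystem
subset: HPO-derived

[Term]
id: PyramidalSigns
name: Pyramidal signs
is_a: AbnormalityOfTheCentralNervousSystem
subset: SNOMED-derived

[Term]
id: ExtrapyramidalSigns
name: Extrapyramidal signs
is_a: AbnormalityOfTheCentralNervousSystem
subset: SNOMED-derived

[Term]
id: PsychiatricDisturbance
name: Psychiatric disturbance
is_a: AbnormalityOfTheCentralNervousSystem
subset: SNOMED-derived

[Term]
id: PeripheralNeuropathy
name: Peripheral neuropathy
is_a: AbnormalityOfTheNervousSystem
subset: HPO-derived

[Term]
id: ExtraNeurologicalManifestation
name: Extra-neurological manifestation
is_a: Phenotype
subset: new

[Term]
id: AbnormalityOfTheDigestiveSystem
name: Abnormality of the digestive system
is_a: ExtraNeurologicalManifestation
subset: HPO-derived

[Term]
id: Diarrhea
name: Diarrhea
is_a: AbnormalityOfTheDigestiveSystem
subset: HPO-derived

[Term]
id: ChronicDiarrhea
name: Chronic diarrhea
is_a: Diarrhea
subset: HPO-derived

[Term]
id: ChildhoodOnsetChronicDiarrhea
name: Childhood-onset chronic diarrhea
is_a: ChronicDiarrhea
subset: new

[Term]
id: Xanthoma
name: Xanthoma
is_a: ExtraNeurologicalManifestation
subset: HPO-derived

[Term]
id: TendonXanthomas
name: Tendon xanthomas
is_a: Xanthoma
synonym: "tendinous xanthoma" EXACT []
subset: HPO-derived

[Term]
id: Cataract
name: Cataract
is_a: ExtraNeurologicalManifestation
subset: HPO-derived

[Term]
id: JuvenileCataracts
name: Juvenile cataracts
is_a: Cataract
subset: HPO-derived

[Term]
id: PrematureArteriosclerosis
name: Premature arteriosclerosis
is_a: ExtraNeurologicalManifestation
subset: SNOMED-derived

[Term]
id: Osteoporosis
name: Osteoporosis
is_a: ExtraNeurologicalManifestation
subset: HPO-derived

[Term]
id: DiagnosticStudyFinding
name: Diagnostic study finding
is_a: Phenotype
subset: new

[Term]
id: AbnormalBrainMRI
name: Abnormal brain MRI
is_a: DiagnosticStudyFinding
subset: SNOMED-derived

[Term]
id: AbnormalEEG
name: Abnormal EEG
is_a: DiagnosticStudyFinding
subset: SNOMED-derived

[Term]
id: ElevatedPlasmaCholestanol
name: Elevated plasma cholestanol
is_a: DiagnosticStudyFinding
subset: new

[Term]
id: AbnormalNerveConduction
name: Abnormal nerve conduction
is_a: DiagnosticStudyFinding
subset: SNOMED-derived

[Term]
id: AnatomicalStructure
name: Anatomical Structure

[Term]
id: Brain
name: Brain
is_a: AnatomicalStructure
subset: SNOMED-derived

[Term]
id: Cerebellum
name: Cerebellum
is_a: Brain
subset: SNOMED-derived

[Term]
id: SpinalCord
name: Spinal cord
is_a: AnatomicalStructure
subset: SNOMED-derived

[Term]
id: PeripheralNerve
name: Peripheral nerve
is_a: AnatomicalStructure
subset: SNOMED-derived

[Term]
id: Tendon
name: Tendon
is_a: AnatomicalStructure
subset: SNOMED-derived

[Term]
id: AchillesTendon
name: Achilles tendon
is_a: Tendon
subset: SNOMED-derived

[Term]
id: Eye
name: Eye
is_a: AnatomicalStructure
subset: SNOMED-derived

[Term]
id: Lens
name: Lens
is_a: Eye
subset: SNOMED-derived

[Term]
id: Intestine
name: Intestine
is_a: AnatomicalStructure
subset: SNOMED-derived

[Term]
id: Artery
name: Artery
is_a: AnatomicalStructure
subset: SNOMED-derived

[Term]
id: Bone
name: Bone
is_a: AnatomicalStructure
subset: SNOMED-derived

[Term]
id: DiagnosticStudy
name: Diagnostic Study

[Term]
id: ImagingStudy
name: Imaging study
is_a: DiagnosticStudy
subset: SNOMED-derived

[Term]
id: BrainMRI
name: Brain MRI
is_a: ImagingStudy
subset: SNOMED-derived

[Term]
id: SpinalMRI
name: Spinal MRI
is_a: ImagingStudy
subset: SNOMED-derived

[Term]
id: ElectrophysiologicalStudy
name: Electrophysiological study
is_a: DiagnosticStudy
subset: SNOMED-derived

[Term]
id: EEG
name: Electroencephalogram
is_a: ElectrophysiologicalStudy
subset: SNOMED-derived

[Term]
id: NerveConductionStudy
name: Nerve conduction study
is_a: ElectrophysiologicalStudy
subset: SNOMED-derived

[Term]
id: LaboratoryTest
name: Laboratory test
is_a: DiagnosticStudy
subset: SNOMED-derived

[Term]
id: CholestanolAssay
name: Cholestanol assay
is_a: LaboratoryTest
subset: new

[Term]
id: GeneticTesting
name: Genetic testing
is_a: LaboratoryTest
subset: SNOMED-derived

[Term]
id: QualifierValue
name: Qualifier Value

[Term]
id: Chronic
name: Chronic
is_a: QualifierValue
subset: SNOMED-derived

[Term]
id: Acute
name: Acute
is_a: QualifierValue
subset: SNOMED-derived

[Term]
id: ChildhoodOnset
name: Childhood onset
is_a: QualifierValue
subset: HPO-derived

[Term]
id: AdultOnset
name: Adult onset
is_a: QualifierValue
subset: HPO-derived

[Term]
id: Juvenile
name: Juvenile
is_a: QualifierValue
subset: SNOMED-derived

[Term]
id: Bilateral
name: Bilateral
is_a: QualifierValue
subset: SNOMED-derived

[Term]
id: Progressive
name: Progressive
is_a: QualifierValue
subset: SNOMED-derived

[Term]
id: Severe
name: Severe
is_a: QualifierValue
subset: SNOMED-derived

[Term]
id: Mild
name: Mild
is_a: QualifierValue
subset: SNOMED-derived
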