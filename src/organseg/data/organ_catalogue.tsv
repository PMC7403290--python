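# organseg organ catalogue, version 1
# columns: name	group	count	kind	singular
# kind: single | bilateral | vertebrae | ribs
Skull	bone	1	single	Skull
Mandible	bone	1	single	Mandible
Cervical vertebrae	bone	7	vertebrae	Cervical vertebrae
Thoracic vertebrae	bone	12	vertebrae	Thoracic vertebrae
Lumbar vertebrae	bone	5	vertebrae	Lumbar vertebrae
Ribs	bone	24	ribs	Rib
Sacrum and coccyx	bone	1	single	Sacrum and coccyx
Hip bones	bone	2	bilateral	Hip bone
Scapulae	bone	2	bilateral	Scapula
Clavicles	bone	2	bilateral	Clavicle
Sternum manubrium	bone	1	single	Sternum manubrium
Sternum body	bone	1	single	Sternum body
Humerus	bone	2	bilateral	Humerus
Radius	bone	2	bilateral	Radius
Ulna	bone	2	bilateral	Ulna
Hand	bone	2	bilateral	Hand
Femur	bone	2	bilateral	Femur
Tibia	bone	2	bilateral	Tibia
Fibula	bone	2	bilateral	Fibula
Patella	bone	2	bilateral	Patella
Foot	bone	2	bilateral	Foot
Adrenal gland	soft_tissue	2	bilateral	Adrenal gland
Brain	soft_tissue	1	single	Brain
Lungs	soft_tissue	2	bilateral	Lung
Trachea	soft_tissue	1	single	Trachea
Bronchi	soft_tissue	2	bilateral	Bronchus
Heart	soft_tissue	1	single	Heart
Aorta	soft_tissue	1	single	Aorta
Ventricle	soft_tissue	1	single	Ventricle
Gastrointestinal tract	soft_tissue	1	single	Gastrointestinal tract
Liver	soft_tissue	1	single	Liver
Gallbladder	soft_tissue	1	single	Gallbladder
Spleen	soft_tissue	1	single	Spleen
Pancreas	soft_tissue	1	single	Pancreas
Kidneys	soft_tissue	2	bilateral	Kidney
Urinary bladder	soft_tissue	1	single	Urinary bladder
Prostate	soft_tissue	1	single	Prostate
Testes	soft_tissue	1	single	Testes
Muscle gluteus maximus	soft_tissue	2	bilateral	Muscle gluteus maximus
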