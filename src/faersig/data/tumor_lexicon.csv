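pt,soc
Basal cell carcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Squamous cell carcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Squamous cell carcinoma of skin,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Malignant melanoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Malignant melanoma in situ,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Skin cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Bowen's disease,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Keratoacanthoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Lymphoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Hodgkin's disease,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Non-Hodgkin's lymphoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Hepatosplenic T-cell lymphoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
B-cell lymphoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
T-cell lymphoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Diffuse large B-cell lymphoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Acute myeloid leukaemia,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Acute lymphocytic leukaemia,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Chronic lymphocytic leukaemia,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Chronic myeloid leukaemia,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Leukaemia,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Myelodysplastic syndrome,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Multiple myeloma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Colon cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Colorectal cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Rectal cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Anal cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Anal squamous cell carcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Gastric cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Oesophageal carcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Pancreatic carcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Hepatic cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Hepatocellular carcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Cholangiocarcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Gastrointestinal carcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Small intestine carcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Lung neoplasm malignant,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Lung adenocarcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Lung squamous cell carcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Small cell lung cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Bronchial carcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Laryngeal cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Breast cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Breast cancer female,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Breast cancer male,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Ovarian cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Uterine cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Cervix carcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Endometrial cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Prostate cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Testicular cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Bladder cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Renal cell carcinoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Renal cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Thyroid cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Papillary thyroid cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Brain neoplasm,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Glioblastoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Meningioma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Astrocytoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Neuroendocrine tumour,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Carcinoid tumour,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Sarcoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Kaposi's sarcoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Liposarcoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Leiomyosarcoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Osteosarcoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Ewing's sarcoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Neoplasm malignant,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Neoplasm,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Metastasis,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Metastases to liver,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Metastases to lung,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Metastases to bone,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Benign neoplasm of skin,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Melanocytic naevus,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Lipoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Uterine leiomyoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Colon adenoma,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Intestinal polyp,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Tongue neoplasm malignant stage unspecified,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
Tonsil cancer,"Neoplasms benign, malignant and unspecified (incl cysts and polyps)"
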